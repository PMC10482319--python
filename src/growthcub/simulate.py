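"""Synthetic data with planted ground truth for the full analysis pipeline.

Emulates the structure of a growth-annotated expression compendium plus a
matching set of coding sequences:

* conditions with growth rates drawn uniformly on a realistic range
  (0.07-1.42 1/h), optional replicate structure with small rate jitter,
  and ALE / mutant strain flags;
* per-gene log-scale expression that is affine in growth rate,
  e_gc = b_g + s_g * mu_c + noise, with a left-skewed slope mixture so the
  resulting GCI distribution is left-skewed;
* coding sequences whose codon-bias strength beta_g is coupled to the
  planted baseline and slope through a softplus link, so CUB rises with
  expression and growth-coupling;
* annotation terms planted preferentially among positive-slope genes.

All generators are deterministic given their seed, and every planted
parameter is recorded in :class:`SyntheticTruth` for recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._codon_tables import AA_TO_CODONS, MULTI_CODON_AAS
from .expr_prep import ExpressionMatrix
from .seq_cub import CdsRecord, CodonWeightTable

#: growth-rate range (1/h) emulated by default
DEFAULT_RATE_RANGE = (0.07, 1.42)
DEFAULT_N_GENES = 3000
DEFAULT_N_CONDITIONS = 50
DEFAULT_NOISE_SD = 0.5
#: slope mixture: fraction of genes with negative growth coupling
DEFAULT_FRAC_NEGATIVE = 0.65

__all__ = [
    "SyntheticTruth",
    "gen_conditions",
    "gen_expression",
    "gen_sequences",
    "gen_annotations",
    "generate_dataset",
    "DEFAULT_RATE_RANGE",
]


@dataclass
class SyntheticTruth:
    """Planted generative parameters, kept for parameter-recovery tests."""

    seed: int
    gene_ids: list[str]
    condition_ids: list[str]
    growth_rates: list[float]
    baselines: list[float]
    slopes: list[float]
    noise_sd: float
    bias_strengths: list[float] = field(default_factory=list)
    alpha_expr: float = 0.0
    gamma_gci: float = 0.0
    planted_terms: dict[str, list[str]] = field(default_factory=dict)
    replicate_plan: dict[str, int] = field(default_factory=dict)
    duplicate_pairs: list[list[str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def gen_conditions(
    n_cond: int = DEFAULT_N_CONDITIONS,
    rate_range: tuple[float, float] = DEFAULT_RATE_RANGE,
    replicate_plan: int | dict[str, int] = 1,
    frac_ale: float = 0.0,
    frac_mutant: float = 0.0,
    seed: int = 0,
    rate_jitter_sd: float = 0.01,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Condition metadata: growth rates uniform on ``rate_range``,
    experiments expanded per replicate plan with small rate jitter,
    ALE/mutant flags assigned by fraction.

    Returns (experiment-level metadata indexed by experiment id, the
    condition-level growth-rate vector).
    """
    lo, hi = rate_range
    if n_cond < 3:
        raise ValueError("need at least 3 conditions")
    if not 0 < lo <= hi:
        raise ValueError("rate range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    cond_ids = [f"cond{i + 1:03d}" for i in range(n_cond)]
    rates = rng.uniform(lo, hi, size=n_cond)
    if isinstance(replicate_plan, int):
        plan = {c: replicate_plan for c in cond_ids}
    else:
        plan = {c: replicate_plan.get(c, 1) for c in cond_ids}
    n_ale = int(round(frac_ale * n_cond))
    n_mut = int(round(frac_mutant * n_cond))
    flagged = rng.permutation(n_cond)
    ale_set = set(flagged[:n_ale])
    mut_set = set(flagged[n_ale : n_ale + n_mut])
    rows = []
    for i, cond in enumerate(cond_ids):
        for r in range(plan[cond]):
            jitter = rng.normal(0.0, rate_jitter_sd) if plan[cond] > 1 else 0.0
            rows.append(
                {
                    "experiment_id": f"{cond}_r{r + 1}",
                    "condition_id": cond,
                    "growth_rate": max(rates[i] + jitter, lo / 10),
                    "alignment_score": 100.0,
                    "is_ale": i in ale_set,
                    "is_mutant_or_ko": i in mut_set,
                }
            )
    meta = pd.DataFrame(rows).set_index("experiment_id")
    return meta, rates


def _sample_slopes(rng: np.random.Generator, n: int, frac_negative: float) -> np.ndarray:
    """Two-component slope mixture, negatively skewed by default: the
    negative component sits at -1.0 (sd 0.5), the positive at +1.5 (sd 0.5)."""
    negative = rng.random(n) < frac_negative
    s = np.where(
        negative,
        rng.normal(-1.0, 0.5, size=n),
        rng.normal(1.5, 0.5, size=n),
    )
    return s


def gen_expression(
    n_genes: int = DEFAULT_N_GENES,
    conditions: pd.DataFrame | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    frac_negative: float = DEFAULT_FRAC_NEGATIVE,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
    n_duplicate_pairs: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Log-scale expression affine in growth rate plus Gaussian noise.

    e_gc = b_g + s_g * mu_c + eps, eps ~ Normal(0, noise_sd^2), where mu_c
    is the experiment's growth rate. Baselines b_g are Normal(baseline_mean,
    baseline_sd); slopes s_g follow the left-skewed mixture. Optionally
    injects exact duplicate columns (for duplicate-detection tests); the
    injected pair ids are recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    if conditions is None:
        conditions, _ = gen_conditions(seed=seed)
    gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    b = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    s = _sample_slopes(rng, n_genes, frac_negative)
    mu = conditions["growth_rate"].to_numpy(dtype=float)
    vals = b[:, None] + s[:, None] * mu[None, :]
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    values = pd.DataFrame(vals, index=gene_ids, columns=conditions.index)
    meta = conditions.copy()
    # duplicates are injected as whole copied conditions (every replicate
    # column copied) so they survive replicate averaging, as real duplicated
    # conditions would; truth records the condition-id pair
    dup_pairs: list[list[str]] = []
    cond_ids = list(dict.fromkeys(conditions["condition_id"]))
    for d in range(n_duplicate_pairs):
        src_cond = cond_ids[int(rng.integers(len(cond_ids)))]
        dup_cond = f"{src_cond}_dup{d + 1}"
        members = list(meta.index[meta["condition_id"] == src_cond])
        for k, exp in enumerate(members, start=1):
            dup_exp = f"{dup_cond}_r{k}"
            values[dup_exp] = values[exp]
            row = meta.loc[exp].copy()
            row["condition_id"] = dup_cond
            meta.loc[dup_exp] = row
        dup_pairs.append([src_cond, dup_cond])
    cond_level = conditions.drop_duplicates("condition_id")
    truth = SyntheticTruth(
        seed=seed,
        gene_ids=gene_ids,
        condition_ids=list(cond_level["condition_id"]),
        growth_rates=[float(x) for x in cond_level["growth_rate"]],
        baselines=[float(x) for x in b],
        slopes=[float(x) for x in s],
        noise_sd=noise_sd,
        replicate_plan=conditions["condition_id"].value_counts().to_dict(),
        duplicate_pairs=dup_pairs,
    )
    return ExpressionMatrix(values, meta, scale_tag="log_tpm"), truth


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def gen_sequences(
    truth: SyntheticTruth,
    weight_table: CodonWeightTable | None = None,
    mean_codons: int = 300,
    alpha_expr: float = 1.0,
    gamma_gci: float = 1.2,
    beta_noise_sd: float = 1.5,
    seed: int | None = None,
) -> list[CdsRecord]:
    """Coding sequences whose codon bias tracks the planted parameters.

    Per gene, the bias strength is beta_g = softplus(alpha_expr * zb +
    gamma_gci * zs + eps) with zb, zs the z-scored baseline and slope and
    eps ~ Normal(0, beta_noise_sd^2) the gene-specific component of codon
    bias that expression and growth-coupling do not explain (real CUB is
    far from fully predicted by expression). Within each synonymous family,
    codon c is drawn with probability proportional to w(c)**beta_g:
    beta = 0 gives uniform synonymous usage, large beta concentrates on the
    preferred codon. Amino-acid content is uniform over the multi-codon
    families; each CDS is ATG + body + TAA, so lengths are divisible by 3
    by construction. Updates ``truth.bias_strengths`` and the coupling
    fields in place.
    """
    if weight_table is None:
        weight_table = CodonWeightTable.example()
    rng = np.random.default_rng(truth.seed + 104729 if seed is None else seed)
    b = np.asarray(truth.baselines)
    s = np.asarray(truth.slopes)
    zb = (b - b.mean()) / b.std()
    zs = (s - s.mean()) / s.std()
    eps = rng.normal(0.0, beta_noise_sd, size=b.size) if beta_noise_sd > 0 else 0.0
    beta = _softplus(alpha_expr * zb + gamma_gci * zs + eps)
    truth.bias_strengths = [float(x) for x in beta]
    truth.alpha_expr = alpha_expr
    truth.gamma_gci = gamma_gci

    families = [AA_TO_CODONS[aa] for aa in MULTI_CODON_AAS]
    fam_weights = [np.array([weight_table[c] for c in codons]) for codons in families]
    records = []
    for gi, gene_id in enumerate(truth.gene_ids):
        n_codons = max(30, int(rng.poisson(mean_codons)))
        fam_idx = rng.integers(len(families), size=n_codons)
        codons = np.empty(n_codons, dtype=object)
        for f in range(len(families)):
            mask = fam_idx == f
            n_f = int(mask.sum())
            if n_f == 0:
                continue
            p = fam_weights[f] ** beta[gi]
            p = p / p.sum()
            picks = rng.choice(len(families[f]), size=n_f, p=p)
            codons[mask] = [families[f][k] for k in picks]
        seq = "ATG" + "".join(codons) + "TAA"
        records.append(CdsRecord(id=gene_id, seq=seq))
    return records


def gen_annotations(
    truth: SyntheticTruth,
    n_terms: int = 20,
    n_planted: int = 2,
    term_size: int = 60,
    enrichment_strength: float = 4.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Annotation table (gene_id, term_id, term_name) with planted terms.

    Planted terms sample members with weight exp(strength) for genes whose
    planted slope is positive (strength 0 reduces to the uniform null);
    background terms sample uniformly. Planted memberships are recorded in
    ``truth.planted_terms``.
    """
    if n_terms < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng(truth.seed + 15485863 if seed is None else seed)
    genes = np.array(truth.gene_ids)
    pos = np.asarray(truth.slopes) > 0
    w_planted = np.where(pos, math.exp(enrichment_strength), 1.0)
    w_planted = w_planted / w_planted.sum()
    rows = []
    truth.planted_terms = {}
    for t in range(n_terms):
        term_id = f"T{t + 1:04d}"
        planted = t < n_planted
        size = min(term_size, len(genes))
        p = w_planted if planted else None
        members = rng.choice(genes, size=size, replace=False, p=p)
        label = "planted_growth_program" if planted else "background"
        for g in members:
            rows.append({"gene_id": g, "term_id": term_id, "term_name": f"{label}_{t + 1}"})
        if planted:
            truth.planted_terms[term_id] = sorted(members.tolist())
    return pd.DataFrame(rows)


def generate_dataset(
    out_dir: str | Path,
    n_genes: int = DEFAULT_N_GENES,
    n_cond: int = DEFAULT_N_CONDITIONS,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    replicate_plan: int | dict[str, int] = 1,
    frac_ale: float = 0.0,
    frac_mutant: float = 0.0,
    n_duplicate_pairs: int = 0,
) -> SyntheticTruth:
    """Generate and write a complete synthetic dataset.

    Writes expr.tsv, meta.tsv, cds.fasta, annotations.tsv, labels.tsv
    (essential-like labels for positive-slope genes), weights.tsv (the
    illustrative CAI table) and truth.json under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conditions, _ = gen_conditions(
        n_cond=n_cond, replicate_plan=replicate_plan,
        frac_ale=frac_ale, frac_mutant=frac_mutant, seed=seed,
    )
    matrix, truth = gen_expression(
        n_genes=n_genes, conditions=conditions, noise_sd=noise_sd,
        seed=seed, n_duplicate_pairs=n_duplicate_pairs,
    )
    table = CodonWeightTable.example()
    records = gen_sequences(truth, table)
    annotations = gen_annotations(truth)

    matrix.write(out / "expr.tsv", out / "meta.tsv")
    with open(out / "cds.fasta", "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")
    annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    labels = pd.DataFrame(
        {
            "gene_id": truth.gene_ids,
            "label": ["essential" if s > 0 else "nonessential" for s in truth.slopes],
        }
    )
    labels.to_csv(out / "labels.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(table.weights.items()), columns=["codon", "weight"]
    ).to_csv(out / "weights.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
    return truth
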