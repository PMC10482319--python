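"""End-to-end orchestration: preprocessing -> CUB scoring -> GCI ->
condition fits -> model battery -> group statistics and enrichment.

A single :class:`RunConfig` drives the run; every stage writes its output
tables plus a JSON manifest recording parameters, seeds, and row/column
counts at each stage, so a rerun with the same config and inputs is
reproducible (bit-identical for deterministic stages, seed-identical for
the stochastic ones).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import expr_prep, gci_stats, group_stats, model_suite, seq_cub

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run."""

    expr_path: str
    meta_path: str
    cds_path: str
    weights_path: str
    out_dir: str
    annotations_path: str | None = None
    labels_path: str | None = None
    cds_format: str = "fasta"
    cub_metric: str = "CAI"
    # input scale: "log" passes values through; "raw_ln"/"raw_log10" apply
    # the 6 + log(a / column total) transform first
    input_scale: str = "log"
    min_alignment: float = 80.0
    sparse_n: int | None = None
    neutral_subsets: bool = False
    max_len_factor: float = 5.0
    enrich_p_max: float = 0.04
    enrich_q_max: float = 0.05
    enrich_top_k: int = 15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        for attr in ("expr_path", "meta_path", "cds_path", "weights_path"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise PipelineError("config", "missing_input", f"{attr}: {p} does not exist")
        for attr in ("annotations_path", "labels_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", "missing_input", f"{attr}: {p} does not exist")
        if not (0 <= self.enrich_p_max <= 1 and 0 <= self.enrich_q_max <= 1):
            raise PipelineError("config", "bad_threshold", "enrichment thresholds must be in [0,1]")
        if self.input_scale not in ("log", "raw_ln", "raw_log10"):
            raise PipelineError("config", "bad_scale", f"unknown input_scale {self.input_scale!r}")


def _stage(manifest: dict, name: str, **info) -> None:
    manifest["stages"].append({"stage": name, **info})


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}

    try:
        # ---- stage 1: preprocessing -------------------------------------
        matrix = expr_prep.load_expression(config.expr_path, config.meta_path)
        n_genes_in, n_cols_in = matrix.n_genes, matrix.n_columns
        if config.input_scale != "log":
            flavor = "six_plus_ln_frac" if config.input_scale == "raw_ln" else "six_plus_log10_frac"
            normed, n_zero = expr_prep.normalize_abundances(matrix.values, flavor)
            matrix = expr_prep.ExpressionMatrix(normed, matrix.meta, scale_tag=flavor)
        else:
            n_zero = 0
        if config.sparse_n is not None and config.sparse_n > matrix.n_columns:
            raise PipelineError("config", "sparse_n_too_large",
                                f"sparse_n={config.sparse_n} exceeds {matrix.n_columns} columns")
        matrix, filt_report = expr_prep.filter_conditions(matrix, config.min_alignment)
        n_after_filter = matrix.n_columns
        matrix = expr_prep.average_replicates(matrix)
        n_after_avg = matrix.n_columns
        matrix, dropped_dups = expr_prep.drop_duplicate_profiles(matrix)
        _stage(
            manifest, "prep",
            genes_in=n_genes_in, columns_in=n_cols_in, zeros_replaced=n_zero,
            filter_report=filt_report,
            columns_after_filter=n_after_filter,
            columns_dropped_by_filter=n_cols_in - n_after_filter,
            conditions_after_averaging=n_after_avg,
            duplicate_columns_dropped=dropped_dups,
            conditions_final=matrix.n_columns,
        )
        if config.sparse_n is not None and config.sparse_n < matrix.n_columns:
            matrix, prune_log = expr_prep.prune_to_sparse(matrix, config.sparse_n, config.seed)
            _stage(manifest, "sparse_prune", removals=len(prune_log),
                   conditions_final=matrix.n_columns)
        matrix.write(out / "expr_prepped.tsv", out / "meta_prepped.tsv")

        # ---- stage 2: CUB scoring ---------------------------------------
        records = seq_cub.read_cds(config.cds_path, config.cds_format)
        kept, removed = seq_cub.filter_cds(records, config.max_len_factor)
        if not kept:
            raise PipelineError("score", "no_cds_survive", "all CDS removed by quality filters")
        table = seq_cub.load_weight_table(config.weights_path, config.cub_metric)
        scores = seq_cub.score_all(kept, [table])
        seq_cub.write_scores(scores, out / "cub_scores.tsv")
        _stage(
            manifest, "score",
            cds_in=len(records), cds_kept=len(kept), cds_removed=len(removed),
            removal_reasons=pd.Series([r for _, r in removed]).value_counts().to_dict()
            if removed else {},
        )

        # ---- stage 3: GCI + permutation null ----------------------------
        cub_series = scores.set_index("gene_id")["value"]
        gene_scores = gci_stats.gene_score_table(
            matrix, {config.cub_metric: cub_series}, seed=config.seed
        )
        gene_scores.to_csv(out / "gene_scores.tsv", sep="\t")
        nulls = gci_stats.null_summary(gene_scores["gci"], gene_scores["gci_permuted"])
        _stage(manifest, "gci", genes=len(gene_scores),
               genes_undefined_gci=int(gene_scores["gci"].isna().sum()), **nulls)

        # ---- stage 4: per-condition fits --------------------------------
        fits = gci_stats.per_condition_cub_fit(matrix, cub_series)
        fits.to_csv(out / "condition_fits.tsv", sep="\t", index=False)
        rho, p = gci_stats.growth_vs_fit_correlation(fits)
        _stage(manifest, "condition_fits", conditions=len(fits),
               spearman_rho=rho, spearman_p=p)

        # ---- stage 5: model battery -------------------------------------
        metric_col = config.cub_metric.lower()
        battery = model_suite.model_battery(
            gene_scores[metric_col], gene_scores["mean_expression"], gene_scores["gci"]
        )
        rows = [battery[m].to_row() for m in model_suite.MODEL_IDS]
        pd.DataFrame(rows).to_csv(out / "model_comparison.tsv", sep="\t", index=False)
        (out / "vif.json").write_text(json.dumps(battery["additive"].vif, indent=1))
        _stage(manifest, "models",
               adj_r2={m: battery[m].adj_r2 for m in model_suite.MODEL_IDS},
               vif=battery["additive"].vif)

        # ---- stage 6: group stats + enrichment --------------------------
        stage6: dict = {}
        neg, pos, n_zero_gci = group_stats.split_by_gci_sign(gene_scores)
        stage6.update(n_gci_negative=len(neg), n_gci_positive=len(pos),
                      n_gci_zero=n_zero_gci)
        if config.labels_path:
            labels = group_stats.load_labels(config.labels_path).set_index("gene_id")["label"]
            common = gene_scores.index.intersection(labels.index)
            groups = labels.loc[common].unique()
            if len(groups) == 2:
                a = gene_scores.loc[common[labels.loc[common] == groups[0]], "gci"].dropna()
                b = gene_scores.loc[common[labels.loc[common] == groups[1]], "gci"].dropna()
                t = group_stats.two_sample_t(a, b)
                stage6["ttest"] = {"groups": list(map(str, groups)), **asdict(t)}
                (out / "ttests.json").write_text(json.dumps(stage6["ttest"], indent=1))
        if config.annotations_path:
            ann = group_stats.load_annotations(config.annotations_path)
            universe = set(gene_scores.index[gene_scores["gci"].notna()])
            for name, gene_set in (("neg", neg), ("pos", pos)):
                if not gene_set:
                    continue
                enr = group_stats.ora_enrichment(
                    gene_set & universe, universe, ann,
                    p_max=config.enrich_p_max, q_max=config.enrich_q_max,
                    top_k=config.enrich_top_k,
                )
                enr.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
                stage6[f"enriched_terms_{name}"] = len(enr)
        _stage(manifest, "group_stats", **stage6)

    except PipelineError:
        (out / "FAILED").write_text(json.dumps(manifest, indent=1, default=str))
        raise
    except Exception as exc:  # noqa: BLE001 - annotate stage context
        stage_name = manifest["stages"][-1]["stage"] if manifest["stages"] else "prep"
        (out / "FAILED").write_text(json.dumps(manifest, indent=1, default=str))
        raise PipelineError(stage_name, type(exc).__name__, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
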