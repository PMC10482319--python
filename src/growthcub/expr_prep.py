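"""Expression-matrix preprocessing with growth-rate metadata.

Loads genes x experiments abundance tables, normalizes raw abundances to a
log scale, filters conditions on growth-rate and alignment-score quality,
averages replicates into conditions, detects and excludes duplicated
expression profiles, iteratively prunes to a maximally distinct ("sparse")
condition subset, and constructs neutral (non-ALE / wild-type) subsets.

The canonical pipeline order is:
normalize -> filter_conditions -> average_replicates ->
detect_duplicate_profiles/exclude -> optional prune/subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ["condition_id", "growth_rate", "alignment_score", "is_ale", "is_mutant_or_ko"]

__all__ = [
    "ExpressionMatrix",
    "load_expression",
    "load_metadata",
    "normalize_abundances",
    "filter_conditions",
    "average_replicates",
    "detect_duplicate_profiles",
    "drop_duplicate_profiles",
    "prune_to_sparse",
    "neutral_subsets",
    "drop_gene_set",
]


@dataclass
class ExpressionMatrix:
    """Genes x experiments log-scale abundance matrix with condition metadata.

    ``values``: DataFrame indexed by gene_id with one column per experiment.
    ``meta``: DataFrame indexed by experiment id, columns condition_id,
    growth_rate, alignment_score, is_ale, is_mutant_or_ko.
    ``scale_tag`` records the normalization applied ("log_tpm",
    "six_plus_ln_frac", "six_plus_log10_frac", "raw").
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("expression columns and metadata rows do not align")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                self.meta[col] = np.nan if col in ("growth_rate", "alignment_score") else False
        self.meta["is_ale"] = self.meta["is_ale"].fillna(False).astype(bool)
        self.meta["is_mutant_or_ko"] = self.meta["is_mutant_or_ko"].fillna(False).astype(bool)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def growth_rates(self) -> np.ndarray:
        return self.meta["growth_rate"].to_numpy(dtype=float)

    def select_columns(self, ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[ids].copy(), self.meta.loc[ids].copy(), self.scale_tag)

    def write(self, expr_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="gene_id")
        self.meta.to_csv(meta_path, sep="\t", index_label="experiment_id")


def load_expression(
    expr_path: str | Path, meta_path: str | Path, scale_tag: str = "log_tpm"
) -> ExpressionMatrix:
    """Load expression TSV (first column gene_id) plus condition metadata TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = load_metadata(meta_path)
    missing = [c for c in values.columns if c not in meta.index]
    if missing:
        raise ValueError(f"experiments without metadata: {missing}")
    return ExpressionMatrix(values, meta.loc[list(values.columns)].copy(), scale_tag)


def load_metadata(meta_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if meta.index.duplicated().any():
        raise ValueError("duplicate experiment ids in metadata")
    return meta


def normalize_abundances(
    raw: pd.DataFrame,
    flavor: Literal["six_plus_ln_frac", "six_plus_log10_frac"],
    zero_policy: Literal["replace_with_min_nonzero", "error"] = "replace_with_min_nonzero",
) -> tuple[pd.DataFrame, int]:
    """Normalize raw nonnegative abundances to 6 + log(a / column total).

    Zeros are replaced by the smallest nonzero value of the whole matrix
    before the transform; the column total is recomputed after replacement
    so per-column fractions sum to 1. Returns (normalized, n_zeros_replaced).
    """
    arr = raw.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("raw abundances must be nonnegative")
    n_zero = int((arr == 0).sum())
    if n_zero:
        if zero_policy == "error":
            raise ValueError(f"{n_zero} zero entries present under zero_policy='error'")
        nonzero = arr[arr > 0]
        if nonzero.size == 0:
            raise ValueError("matrix is all zeros")
        arr = np.where(arr == 0, nonzero.min(), arr)
    totals = arr.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("degenerate all-zero column")
    frac = arr / totals
    log = np.log(frac) if flavor == "six_plus_ln_frac" else np.log10(frac)
    if flavor not in ("six_plus_ln_frac", "six_plus_log10_frac"):
        raise ValueError(f"unknown flavor {flavor!r}")
    return pd.DataFrame(6.0 + log, index=raw.index, columns=raw.columns), n_zero


def filter_conditions(
    matrix: ExpressionMatrix,
    min_alignment: float = 80.0,
    require_positive_growth: bool = True,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Drop columns with unknown/zero growth rate or poor alignment score.

    Returns the filtered matrix and a report counting removals per reason.
    Columns lacking an alignment score are not penalized for it.
    """
    report = {"missing_growth": 0, "zero_growth": 0, "low_alignment": 0}
    keep: list[str] = []
    for exp_id, row in matrix.meta.iterrows():
        g = row["growth_rate"]
        if require_positive_growth and (pd.isna(g)):
            report["missing_growth"] += 1
            continue
        if require_positive_growth and g <= 0:
            report["zero_growth"] += 1
            continue
        a = row["alignment_score"]
        if not pd.isna(a) and a < min_alignment:
            report["low_alignment"] += 1
            continue
        keep.append(exp_id)
    if not keep:
        raise ValueError("all conditions removed by quality filters")
    return matrix.select_columns(keep), report


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate experiments to one column per condition_id.

    Expression values (on the stored log scale) and growth rates are
    arithmetically averaged; strain flags are merged by logical OR.
    Output column order follows first appearance of each condition.
    """
    if matrix.meta["condition_id"].isna().any():
        raise ValueError("every column needs a condition_id before averaging")
    order = list(dict.fromkeys(matrix.meta["condition_id"]))
    cols, meta_rows = {}, []
    for cond in order:
        members = matrix.meta.index[matrix.meta["condition_id"] == cond]
        cols[cond] = matrix.values[members].mean(axis=1)
        sub = matrix.meta.loc[members]
        meta_rows.append(
            {
                "condition_id": cond,
                "growth_rate": sub["growth_rate"].mean(),
                "alignment_score": sub["alignment_score"].mean(),
                "is_ale": bool(sub["is_ale"].any()),
                "is_mutant_or_ko": bool(sub["is_mutant_or_ko"].any()),
            }
        )
    meta = pd.DataFrame(meta_rows, index=pd.Index(order, name="experiment_id"))
    return ExpressionMatrix(pd.DataFrame(cols, index=matrix.values.index), meta, matrix.scale_tag)


def _spearman_matrix(values: pd.DataFrame) -> np.ndarray:
    ranks = values.rank(axis=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(ranks, rowvar=False)


def detect_duplicate_profiles(
    matrix: ExpressionMatrix, method: Literal["spearman"] = "spearman", tol: float = 0.0
) -> tuple[list[tuple[str, str]], list[str]]:
    """All-by-all Spearman correlation; pairs with rho >= 1 - tol are duplicates.

    Returns (duplicate pairs, constant columns with undefined correlation).
    Constant columns are reported separately, never flagged as duplicates.
    """
    if matrix.n_columns < 2:
        raise ValueError("need at least 2 columns")
    cols = list(matrix.values.columns)
    constant = [c for c in cols if matrix.values[c].nunique() <= 1]
    rho = _spearman_matrix(matrix.values)
    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if cols[i] in constant or cols[j] in constant:
                continue
            if rho[i, j] >= 1.0 - tol - 1e-12:
                pairs.append((cols[i], cols[j]))
    return pairs, constant


def drop_duplicate_profiles(
    matrix: ExpressionMatrix, policy: Literal["drop_both", "keep_one"] = "drop_both"
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove duplicated expression profiles (default drops both members)."""
    pairs, _ = detect_duplicate_profiles(matrix)
    drop: set[str] = set()
    for a, b in pairs:
        drop.update((a, b) if policy == "drop_both" else (b,))
    keep = [c for c in matrix.values.columns if c not in drop]
    if not keep:
        raise ValueError("duplicate removal would drop every column")
    return matrix.select_columns(keep), sorted(drop)


def prune_to_sparse(
    matrix: ExpressionMatrix, target_n: int, seed: int
) -> tuple[ExpressionMatrix, list[dict]]:
    """Iteratively remove one member of the most-correlated condition pair.

    Each iteration computes the all-by-all Spearman matrix, finds the pair
    with the highest correlation (lexicographically smallest pair on ties),
    and removes one member chosen uniformly at random under ``seed``, until
    ``target_n`` columns remain. Returns the pruned matrix and a removal log.
    """
    if not 2 <= target_n <= matrix.n_columns:
        raise ValueError("target_n must be in [2, current column count]")
    rng = np.random.default_rng(seed)
    current = matrix
    log: list[dict] = []
    it = 0
    while current.n_columns > target_n:
        it += 1
        cols = list(current.values.columns)
        rho = _spearman_matrix(current.values)
        np.fill_diagonal(rho, -np.inf)
        rho = np.where(np.isnan(rho), -np.inf, rho)
        best = -np.inf
        best_pair: tuple[str, str] | None = None
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                pair = tuple(sorted((cols[i], cols[j])))
                if rho[i, j] > best or (
                    rho[i, j] == best and (best_pair is None or pair < best_pair)
                ):
                    best, best_pair = rho[i, j], pair
        assert best_pair is not None
        removed = best_pair[int(rng.integers(2))]
        log.append({"iteration": it, "pair": list(best_pair), "removed": removed, "rho": float(best)})
        current = current.select_columns([c for c in cols if c != removed])
    return current, log


def neutral_subsets(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """(non-ALE subset, non-ALE wild-type subset) by strain flags."""
    non_ale_ids = [c for c in matrix.values.columns if not matrix.meta.loc[c, "is_ale"]]
    wt_ids = [c for c in non_ale_ids if not matrix.meta.loc[c, "is_mutant_or_ko"]]
    return matrix.select_columns(non_ale_ids), matrix.select_columns(wt_ids)


def drop_gene_set(matrix: ExpressionMatrix, gene_ids: set[str]) -> tuple[ExpressionMatrix, dict]:
    """Remove a gene set (e.g. AT-rich outliers); absent ids only logged."""
    present = set(matrix.values.index)
    removable = present & set(gene_ids)
    absent = len(set(gene_ids) - present)
    if absent:
        logger.warning("%d ids to drop were not in the matrix", absent)
    kept = matrix.values.drop(index=list(removable))
    report = {"removed": len(removable), "absent": absent}
    return ExpressionMatrix(kept, matrix.meta.copy(), matrix.scale_tag), report
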