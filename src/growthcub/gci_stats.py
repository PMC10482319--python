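"""Growth Correlation Index (GCI) and condition-level correlation structure.

The GCI of a gene is the Pearson correlation between its expression level
and the population growth rate across conditions: positive GCI genes are
relatively upregulated under rapid growth, negative GCI genes under slow
growth. A per-gene permutation null (one shuffled pairing per gene) gives
a reference distribution centered at zero. Condition-level summaries cover
the all-by-all expression R-squared matrix, the per-condition strength of
the expression-CUB relationship, and its Spearman correlation with growth
rate.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .expr_prep import ExpressionMatrix

__all__ = [
    "pairwise_condition_r2",
    "gci",
    "gci_vector",
    "gci_permutation_null",
    "per_condition_cub_fit",
    "growth_vs_fit_correlation",
    "doubling_time",
    "null_summary",
    "gene_score_table",
]


def pairwise_condition_r2(matrix: ExpressionMatrix) -> pd.DataFrame:
    """All-by-all squared Pearson correlation between condition columns.

    Constant columns yield NaN entries (undefined, never silently 0);
    the diagonal is 1 for non-constant columns.
    """
    if matrix.n_columns < 2:
        raise ValueError("need at least 2 columns")
    vals = matrix.values.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals, rowvar=False)
    r2 = r**2
    bad = sd == 0
    r2[bad, :] = np.nan
    r2[:, bad] = np.nan
    np.fill_diagonal(r2, np.where(bad, np.nan, 1.0))
    cols = matrix.values.columns
    return pd.DataFrame(r2, index=cols, columns=cols)


def gci(expr: np.ndarray, growth: np.ndarray) -> float:
    """Pearson correlation of one gene's expression with growth rate.

    Returns NaN when either vector is constant or fewer than 3 paired
    observations exist (the index is then undefined, not zero).
    """
    expr = np.asarray(expr, dtype=float)
    growth = np.asarray(growth, dtype=float)
    if expr.shape != growth.shape:
        raise ValueError("expression and growth vectors differ in length")
    ok = ~(np.isnan(expr) | np.isnan(growth))
    expr, growth = expr[ok], growth[ok]
    if expr.size < 3 or expr.std() == 0 or growth.std() == 0:
        return float("nan")
    return float(np.corrcoef(expr, growth)[0, 1])


def gci_vector(matrix: ExpressionMatrix, growth: np.ndarray | None = None) -> pd.Series:
    """GCI for every gene in the matrix (vectorized Pearson r)."""
    g = matrix.growth_rates if growth is None else np.asarray(growth, dtype=float)
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[1] != g.size:
        raise ValueError("growth vector does not match column count")
    if vals.shape[1] < 3:
        return pd.Series(np.nan, index=matrix.values.index, name="gci")
    gc = g - g.mean()
    xc = vals - vals.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1)) * math.sqrt((gc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ gc) / denom
    r[denom == 0] = np.nan
    if gc.std() == 0:
        r[:] = np.nan
    return pd.Series(r, index=matrix.values.index, name="gci")


def gci_permutation_null(
    matrix: ExpressionMatrix, growth: np.ndarray | None = None, seed: int = 0
) -> pd.Series:
    """One permuted GCI per gene: expression values re-paired with growth
    rates under an independent uniform permutation per gene."""
    g = matrix.growth_rates if growth is None else np.asarray(growth, dtype=float)
    rng = np.random.default_rng(seed)
    vals = matrix.values.to_numpy(dtype=float)
    n_genes, n_cond = vals.shape
    perms = np.argsort(rng.random((n_genes, n_cond)), axis=1)
    shuffled = np.take_along_axis(vals, perms, axis=1)
    perm_matrix = ExpressionMatrix(
        pd.DataFrame(shuffled, index=matrix.values.index, columns=matrix.values.columns),
        matrix.meta.copy(),
        matrix.scale_tag,
    )
    out = gci_vector(perm_matrix, g)
    out.name = "gci_permuted"
    return out


def null_summary(observed: pd.Series, permuted: pd.Series) -> dict:
    """Describe the permutation null and where the observed GCI sit.

    Reports the null mean and sd and the fraction of observed values lying
    outside null mean +/- 2 sd (descriptive; no significance claim).
    """
    null = permuted.dropna().to_numpy()
    obs = observed.dropna().to_numpy()
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    outside = float(np.mean((obs < mean - 2 * sd) | (obs > mean + 2 * sd)))
    return {
        "null_mean": mean,
        "null_sd": sd,
        "null_n": int(null.size),
        "frac_observed_outside_2sd": outside,
    }


def per_condition_cub_fit(matrix: ExpressionMatrix, cub: pd.Series) -> pd.DataFrame:
    """Per condition, R-squared of the simple OLS fit of CUB on expression.

    For a simple linear regression this equals the squared Pearson r between
    the CUB metric and that condition's expression column. Genes missing
    from either side are excluded pairwise; conditions with fewer than 3
    usable genes get NaN.
    """
    common = matrix.values.index.intersection(cub.dropna().index)
    if len(common) < 3:
        raise ValueError("need CUB values for at least 3 genes present in the matrix")
    sub = matrix.values.loc[common]
    c = cub.loc[common].to_numpy(dtype=float)
    rows = []
    for col in sub.columns:
        x = sub[col].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(c))
        r2 = np.nan
        if ok.sum() >= 3 and x[ok].std() > 0 and c[ok].std() > 0:
            r2 = float(np.corrcoef(x[ok], c[ok])[0, 1] ** 2)
        rows.append(
            {
                "condition_id": col,
                "growth_rate": float(matrix.meta.loc[col, "growth_rate"]),
                "expr_cub_r2": r2,
            }
        )
    return pd.DataFrame(rows)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman rho at small n.

    Enumerates all n! pairings of the (tie-averaged) rank vectors; the
    p-value is the fraction of pairings whose |rho| reaches the observed.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    a = rx - rx.mean()
    b = ry - ry.mean()
    num = b[perms] @ a
    denom = math.sqrt((a**2).sum() * (b**2).sum())
    rhos = num / denom
    observed = abs(np.corrcoef(rx, ry)[0, 1])
    return float(np.mean(np.abs(rhos) >= observed - 1e-12))


def growth_vs_fit_correlation(table: pd.DataFrame, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman correlation between growth rate and per-condition fit R2.

    Uses exact permutation enumeration for n <= ``exact_max_n`` (the
    t-approximation is unreliable there) and the t-approximation otherwise.
    """
    clean = table.dropna(subset=["growth_rate", "expr_cub_r2"])
    if len(clean) < 4:
        raise ValueError("need at least 4 conditions with defined fits")
    g = clean["growth_rate"].to_numpy()
    r2 = clean["expr_cub_r2"].to_numpy()
    if np.unique(g).size == 1 or np.unique(r2).size == 1:
        raise ValueError("degenerate (all-tied) input; Spearman undefined")
    rho, p = stats.spearmanr(g, r2)
    if len(clean) <= exact_max_n:
        p = _spearman_exact_p(g, r2)
    return float(rho), float(p)


def doubling_time(rate: float) -> float:
    """Population doubling time in hours: ln(2) / growth rate (1/h)."""
    if rate <= 0:
        raise ValueError("growth rate must be positive")
    return math.log(2) / rate


def gene_score_table(
    matrix: ExpressionMatrix,
    cub_scores: dict[str, pd.Series],
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the per-gene score table: mean expression, GCI, permuted GCI,
    and one column per CUB metric (e.g. cai, tai)."""
    out = pd.DataFrame(index=matrix.values.index)
    out["mean_expression"] = matrix.values.mean(axis=1)
    out["gci"] = gci_vector(matrix)
    out["gci_permuted"] = gci_permutation_null(matrix, seed=seed)
    for name, series in cub_scores.items():
        out[name.lower()] = series.reindex(out.index)
    out.index.name = "gene_id"
    return out
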