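"""Group comparisons and over-representation analysis on GCI gene sets.

Compares GCI distributions between gene classes (essential vs
nonessential, core vs accessory) with a pooled-variance Student's t-test,
splits genes by GCI sign, and tests annotation terms for over-representation
in a gene set with the hypergeometric upper tail, Benjamini-Hochberg
correction, and odds-ratio ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TTestResult",
    "two_sample_t",
    "split_by_gci_sign",
    "bh_adjust",
    "ora_enrichment",
    "load_annotations",
    "load_labels",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def two_sample_t(a, b, variant: str = "pooled") -> TTestResult:
    """Two-sided Student's t-test for a difference in means.

    ``variant='pooled'`` assumes equal variances (df = n_a + n_b - 2);
    ``'welch'`` is available for unequal variances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    equal_var = variant == "pooled"
    if equal_var:
        pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        if pooled == 0:
            raise ValueError("zero pooled variance; t-test degenerate")
        df = float(a.size + b.size - 2)
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb == 0:
            raise ValueError("zero variance; t-test degenerate")
        df = float((va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1)))
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(t), df, float(p), float(a.mean()), float(b.mean()),
                       int(a.size), int(b.size))


def split_by_gci_sign(scores: pd.DataFrame) -> tuple[set[str], set[str], int]:
    """Split gene ids into (GCI<0, GCI>0) sets; GCI exactly 0 joins neither.

    Returns (negative set, positive set, count of excluded zero-GCI genes).
    Genes with undefined (NaN) GCI are ignored.
    """
    g = scores["gci"].dropna()
    neg = set(g.index[g < 0])
    pos = set(g.index[g > 0])
    n_zero = int((g == 0).sum())
    return neg, pos, n_zero


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order
    preserved."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def load_annotations(path) -> pd.DataFrame:
    """Annotation TSV with columns gene_id, term_id (term_name optional)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError("annotation table needs columns gene_id, term_id")
    return df


def load_labels(path) -> pd.DataFrame:
    """Label TSV with columns gene_id, label (one classification scheme)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "label"} <= set(df.columns):
        raise ValueError("label table needs columns gene_id, label")
    if df["gene_id"].duplicated().any():
        raise ValueError("a gene may carry at most one label per scheme")
    return df


def ora_enrichment(
    query_set: set[str],
    universe: set[str],
    annotations: pd.DataFrame,
    p_max: float = 0.04,
    q_max: float = 0.05,
    top_k: int = 15,
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis with BH correction.

    For each term with members in the universe: p is the upper-tail
    probability P(X >= k) of drawing k or more term members in a sample of
    n = |query| from N = |universe| containing K term members; q is the
    BH adjustment over all tested terms; the odds ratio comes from the 2x2
    table (k, n-k; K-k, N-K-n+k), reported as inf when a zero cell makes it
    so. Rows failing p <= p_max or q <= q_max are dropped and the survivors
    are ranked by odds ratio descending (top_k rows returned; pass
    ``top_k=None`` for all).
    """
    if not query_set or not universe:
        raise ValueError("query set and universe must be nonempty")
    if not query_set <= universe:
        raise ValueError("query set must be a subset of the universe")
    ann = annotations[annotations["gene_id"].isin(universe)]
    N = len(universe)
    n = len(query_set)
    rows = []
    for term_id, sub in ann.groupby("term_id", sort=True):
        members = set(sub["gene_id"])
        K = len(members)
        k = len(members & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b_, c, d = k, n - k, K - k, N - K - n + k
        if b_ == 0 or c == 0:
            odds = float("inf") if a > 0 and d > 0 else float("nan")
        else:
            odds = (a * d) / (b_ * c)
        name = sub["term_name"].iloc[0] if "term_name" in sub.columns else term_id
        rows.append(
            {"term_id": term_id, "term_name": name, "k_in_set": k, "n_set": n,
             "K_term": K, "N_universe": N, "p": p, "odds_ratio": odds}
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = bh_adjust(table["p"].to_numpy())
    table = table[(table["p"] <= p_max) & (table["q"] <= q_max)]
    table = table.sort_values(["odds_ratio", "term_id"], ascending=[False, True])
    if top_k is not None:
        table = table.head(top_k)
    return table.reset_index(drop=True)
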