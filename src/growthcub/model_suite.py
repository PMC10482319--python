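"""Linear model battery predicting codon usage bias.

Four nested ordinary-least-squares models with the CUB metric (CAI or tAI)
as response: (1) mean expression only, (2) GCI only, (3) both predictors
additively, (4) both plus their interaction. Models are compared by
adjusted R-squared; the additive model additionally carries variance
inflation factors (VIF) as a collinearity diagnostic. Predictors enter on
their stored scales (log mean expression, raw GCI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

MODEL_IDS = ("expr_only", "gci_only", "additive", "interaction")

__all__ = ["ModelFit", "ols_fit", "model_battery", "vif", "linear_vs_quadratic_aic", "MODEL_IDS"]


@dataclass
class ModelFit:
    """One fitted linear model and its summary statistics."""

    model_id: str
    coefficients: dict[str, float]
    r2: float
    adj_r2: float
    p_overall: float
    n: int
    vif: dict[str, float] | None = None
    std_errors: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"model_id": self.model_id, "n": self.n, "r2": self.r2,
               "adj_r2": self.adj_r2, "p_overall": self.p_overall}
        row.update({f"coef_{k}": v for k, v in self.coefficients.items()})
        return row


class SingularDesignError(ValueError):
    """The design matrix is rank-deficient (perfectly collinear columns)."""


def ols_fit(y: np.ndarray, predictors: dict[str, np.ndarray], model_id: str = "custom") -> ModelFit:
    """Ordinary least squares with intercept; returns coefficients, R2,
    adjusted R2 and the overall F-test p-value.

    Rows with missing values must be excluded upstream. A rank-deficient
    design raises :class:`SingularDesignError` naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    names = list(predictors)
    X = np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in response or predictors")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError(f"rank-deficient design over columns {names}")
    res = sm.OLS(y, design).fit()
    coef = {"intercept": float(res.params[0])}
    se = {"intercept": float(res.bse[0])}
    for i, name in enumerate(names, start=1):
        coef[name] = float(res.params[i])
        se[name] = float(res.bse[i])
    return ModelFit(
        model_id=model_id,
        coefficients=coef,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        p_overall=float(res.f_pvalue),
        n=n,
        std_errors=se,
    )


def vif(predictors: dict[str, np.ndarray]) -> dict[str, float]:
    """Variance inflation factors: VIF_k = 1 / (1 - R2 of predictor k
    regressed on the others). Perfect collinearity reports inf."""
    names = list(predictors)
    if len(names) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    arrs = {k: np.asarray(v, dtype=float) for k, v in predictors.items()}
    for k, v in arrs.items():
        if v.std() == 0:
            raise ValueError(f"predictor {k!r} is constant")
    out: dict[str, float] = {}
    for k in names:
        others = {o: arrs[o] for o in names if o != k}
        X = sm.add_constant(np.column_stack(list(others.values())), has_constant="add")
        r2 = float(sm.OLS(arrs[k], X).fit().rsquared)
        out[k] = float("inf") if r2 >= 1.0 - 1e-14 else 1.0 / (1.0 - r2)
    return out


def model_battery(
    cub: pd.Series | np.ndarray,
    mean_expr: pd.Series | np.ndarray,
    gci: pd.Series | np.ndarray,
) -> dict[str, ModelFit]:
    """Fit the four CUB-prediction models on a common gene set.

    Genes with a missing value in any of the three inputs are excluded
    listwise so adjusted R2 values are comparable across the battery.
    """
    y = np.asarray(cub, dtype=float)
    e = np.asarray(mean_expr, dtype=float)
    g = np.asarray(gci, dtype=float)
    if not (y.size == e.size == g.size):
        raise ValueError("inputs must align on the same gene set")
    ok = ~(np.isnan(y) | np.isnan(e) | np.isnan(g))
    y, e, g = y[ok], e[ok], g[ok]
    fits = {
        "expr_only": ols_fit(y, {"expr": e}, "expr_only"),
        "gci_only": ols_fit(y, {"gci": g}, "gci_only"),
        "additive": ols_fit(y, {"expr": e, "gci": g}, "additive"),
        "interaction": ols_fit(y, {"expr": e, "gci": g, "expr_x_gci": e * g}, "interaction"),
    }
    fits["additive"].vif = vif({"expr": e, "gci": g})
    return fits


def linear_vs_quadratic_aic(y: np.ndarray, x: np.ndarray) -> dict[str, float]:
    """AIC comparison of a linear vs quadratic fit of y on x (e.g. CAI~GCI);
    the lower AIC wins. Quadratic is the only nonlinear alternative fitted."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    quad = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
    return {"aic_linear": float(lin.aic), "aic_quadratic": float(quad.aic)}
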