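"""Point predictions and prediction intervals for unknown taxa.

Three methods are implemented:

* **OLS predictive equation** — plug the target's predictors into the fitted
  coefficients; classical prediction interval
  ``sigma2 * (1 + x_h' (X'X)^-1 x_h)``.
* **PGLS predictive equation** — same plug-in point from PGLS coefficients;
  its "generic" interval treats the target as attached at the root with a
  terminal branch equal to the mean root-to-tip path, i.e. the
  phylogenetically informed interval evaluated at ``V_h = 0``.
* **Phylogenetically informed prediction** — the plug-in point adjusted by
  ``eps_u = V_h' V^-1 (Y - X beta)``, the GLS conditional expectation (BLUP)
  of the target's residual given the observed taxa's residuals.  Its
  prediction variance follows Garland & Ives:
  ``sigma2 * (v_hh - V_h' V^-1 V_h) + sigma2 * d' (X' V^-1 X)^-1 d`` with
  ``d = x_h - X' V^-1 V_h``.

All intervals use Student's t with n - p degrees of freedom by default
(``dist="z"`` switches to the normal).  Covariances between the target and
the fitting taxa are multiplied by the fit's lambda; the target's
self-variance ``v_hh`` is left untransformed, consistent with lambda acting
on off-diagonal elements only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .pgls import DesignSpec, RegressionFit, design_row, fit_pgls_ml_lambda, fit_ols
from .tree import CovarianceStructure, Phylogeny, vcv

__all__ = [
    "TargetSpec",
    "PredictionResult",
    "target_from_tree",
    "predict_equation",
    "predict_phylo_informed",
    "loo_self_validation",
]


@dataclass
class TargetSpec:
    """An unknown taxon: predictor values plus phylogenetic position.

    ``v_h`` holds untransformed covariances between the target and each
    fitting taxon (ordered like the fit); ``v_hh`` the target's root-to-tip
    path length.  An all-zero ``v_h`` means the target attaches at the root.
    """

    label: str
    x_values: dict
    v_h: np.ndarray | None = None
    v_hh: float | None = None

    def validate_against(self, fit: RegressionFit) -> None:
        if self.v_h is not None and len(self.v_h) != fit.n:
            raise ValueError(
                f"covariance vector length {len(self.v_h)} does not match "
                f"fit with n={fit.n} taxa"
            )


@dataclass
class PredictionResult:
    method: str  # ols_equation | pgls_equation | phylo_informed
    label: str
    point: float
    epsilon_u: float
    variance: float
    lower: float
    upper: float
    df: int
    alpha: float

    def as_row(self) -> dict:
        return {
            "taxon": self.label,
            "method": self.method,
            "point": self.point,
            "epsilon_u": self.epsilon_u,
            "variance": self.variance,
            "pi_low": self.lower,
            "pi_high": self.upper,
        }


def target_from_tree(
    tree_or_cov: Phylogeny | CovarianceStructure,
    fit_taxa: list[str],
    label: str,
    x_values: dict,
) -> TargetSpec:
    """Build a TargetSpec for a taxon present in the tree, against ``fit_taxa``."""
    cov = vcv(tree_or_cov) if isinstance(tree_or_cov, Phylogeny) else tree_or_cov
    v_h, v_hh = cov.cross(label, fit_taxa)
    return TargetSpec(label=label, x_values=x_values, v_h=v_h, v_hh=v_hh)


def _crit(alpha: float, df: int, dist: str) -> float:
    if dist == "t":
        return float(stats.t.ppf(1.0 - alpha / 2.0, df))
    if dist == "z":
        return float(stats.norm.ppf(1.0 - alpha / 2.0))
    raise ValueError(f"dist must be 't' or 'z', got {dist!r}")


def _xrow(fit: RegressionFit, target: TargetSpec) -> np.ndarray:
    return design_row(fit.design_info, target.x_values)


def predict_equation(
    fit: RegressionFit,
    target: TargetSpec,
    mode: str = "ols",
    alpha: float = 0.05,
    dist: str = "t",
) -> PredictionResult:
    """Plug-in prediction from fitted coefficients only.

    ``mode="ols"`` gives the classical OLS interval and requires an OLS fit;
    ``mode="pgls_generic"`` gives the root-attachment interval of a GLS/PGLS
    fit (the target is treated as phylogenetically average).
    """
    x_h = _xrow(fit, target)
    point = float(x_h @ fit.params.to_numpy())

    if mode == "ols":
        if fit.method != "ols":
            raise ValueError("mode='ols' requires an OLS fit")
        var = fit.sigma2 * (1.0 + float(x_h @ fit.xtvix_inv @ x_h))
    elif mode == "pgls_generic":
        if fit.V is None:
            raise ValueError("mode='pgls_generic' requires a GLS/PGLS fit")
        v_hh = float(np.mean(np.diag(fit.V.V)))
        var = fit.sigma2 * (v_hh + float(x_h @ fit.xtvix_inv @ x_h))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    crit = _crit(alpha, fit.df_resid, dist)
    half = crit * math.sqrt(var)
    method = "ols_equation" if mode == "ols" else "pgls_equation"
    return PredictionResult(
        method, target.label, point, 0.0, var, point - half, point + half,
        fit.df_resid, alpha,
    )


def predict_phylo_informed(
    fit: RegressionFit,
    target: TargetSpec,
    alpha: float = 0.05,
    dist: str = "t",
) -> PredictionResult:
    """BLUP-adjusted prediction with the Garland & Ives interval."""
    if fit.V is None:
        raise ValueError("phylogenetically informed prediction requires a GLS/PGLS fit")
    target.validate_against(fit)
    if target.v_h is None or target.v_hh is None:
        raise ValueError("target lacks phylogenetic covariances (v_h, v_hh)")

    lam = fit.lam if fit.lam is not None else 1.0
    v_h = np.asarray(target.v_h, float) * lam
    v_hh = float(target.v_hh)

    V = fit.V.V
    L = linalg.cholesky(V, lower=True)
    # a = V^-1 v_h via two triangular solves
    a = linalg.cho_solve((L, True), v_h)
    resid = fit.resid.to_numpy()
    eps_u = float(v_h @ linalg.cho_solve((L, True), resid))

    x_h = _xrow(fit, target)
    point = float(x_h @ fit.params.to_numpy()) + eps_u

    X = fit.X
    d = x_h - X.T @ a
    cond = v_hh - float(v_h @ a)
    if cond < -1e-10:
        raise ValueError(f"negative conditional variance {cond}")
    cond = max(cond, 0.0)
    var = fit.sigma2 * cond + fit.sigma2 * float(d @ fit.xtvix_inv @ d)

    crit = _crit(alpha, fit.df_resid, dist)
    half = crit * math.sqrt(var)
    return PredictionResult(
        "phylo_informed", target.label, point, eps_u, var,
        point - half, point + half, fit.df_resid, alpha,
    )


def loo_self_validation(
    table: pd.DataFrame,
    design: DesignSpec,
    tree: Phylogeny | CovarianceStructure,
    alpha: float = 0.05,
    dist: str = "t",
    refit: bool = False,
) -> pd.DataFrame:
    """Leave-one-out self-validation of the three prediction methods.

    One global PGLS fit provides coefficients and lambda (unless
    ``refit=True``, which refits per left-out taxon); each taxon is then
    predicted phylogenetically from the remaining taxa's residuals, with the
    covariance structure re-subset accordingly.  Companion errors from the
    OLS and PGLS predictive equations are included.
    """
    base = vcv(tree) if isinstance(tree, Phylogeny) else tree
    taxa = [t for t in base.taxon_order if t in set(table.index)]
    table = table.loc[taxa]
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa for self-validation")

    global_pgls = fit_pgls_ml_lambda(table, design, base.restrict(taxa))
    global_ols = fit_ols(table, design)
    y, X, dinfo = design.matrices(table)
    n = len(taxa)

    rows = []
    for i, label in enumerate(taxa):
        others = [t for t in taxa if t != label]
        x_vals = {c: table.loc[label, c] for c in table.columns}
        actual = float(y[i])

        if refit:
            fit_i = fit_pgls_ml_lambda(table.loc[others], design, base.restrict(others))
        else:
            fit_i = _subset_fit(global_pgls, base, others, design, table)
        ols_i = fit_ols(table.loc[others], design) if refit else _subset_ols(
            global_ols, others, design, table
        )

        tgt = target_from_tree(base, others, label, x_vals)
        p_phylo = predict_phylo_informed(fit_i, tgt, alpha=alpha, dist=dist)
        p_pgls = predict_equation(fit_i, tgt, mode="pgls_generic", alpha=alpha, dist=dist)
        p_ols = predict_equation(ols_i, tgt, mode="ols", alpha=alpha, dist=dist)

        for res in (p_ols, p_pgls, p_phylo):
            rows.append(
                {
                    "taxon": label,
                    "method": res.method,
                    "actual": actual,
                    "predicted": res.point,
                    "error": actual - res.point,
                    "pi_low": res.lower,
                    "pi_high": res.upper,
                }
            )
    return pd.DataFrame(rows)


def _subset_fit(
    global_fit: RegressionFit,
    base: CovarianceStructure,
    others: list[str],
    design: DesignSpec,
    table: pd.DataFrame,
) -> RegressionFit:
    """Freeze the global coefficients and lambda; re-subset residuals and V.

    Mirrors the literal self-validation procedure: the model is fit once on
    the full data set and only the phylogenetic weighting is adjusted per
    left-out taxon.
    """
    from .tree import transform_lambda
    import copy

    lam = global_fit.lam if global_fit.lam is not None else 1.0
    sub_cov = transform_lambda(base.restrict(others), lam)
    fit = copy.copy(global_fit)
    fit.V = sub_cov
    fit.resid = global_fit.resid.loc[others]
    fit.taxa = list(others)
    fit.n = len(others)
    y, X, dinfo = design.matrices(table.loc[others])
    L = linalg.cholesky(sub_cov.V, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    fit.xtvix_inv = np.linalg.inv(Xw.T @ Xw)
    fit.X = X
    return fit


def _subset_ols(
    global_fit: RegressionFit,
    others: list[str],
    design: DesignSpec,
    table: pd.DataFrame,
) -> RegressionFit:
    import copy

    fit = copy.copy(global_fit)
    y, X, _ = design.matrices(table.loc[others])
    fit.n = len(others)
    fit.taxa = list(others)
    fit.xtvix_inv = np.linalg.inv(X.T @ X)
    fit.X = X
    fit.resid = global_fit.resid.loc[others]
    return fit
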