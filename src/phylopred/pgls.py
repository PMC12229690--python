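"""Ordinary and phylogenetic generalized least squares with ML Pagel's lambda.

The GLS estimator is ``beta = (X' V^-1 X)^-1 X' V^-1 Y`` with ``V`` the
phylogenetic variance-covariance matrix; lambda scales the off-diagonal of
``V`` and is estimated by maximising the Gaussian profile log-likelihood on
[0, 1].  Everything is solved through a Cholesky factor of ``V`` (whitening);
``V`` is never inverted explicitly outside of test oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import DesignInfo, dmatrices
from scipy import linalg, optimize, stats

from .tree import CovarianceStructure, Phylogeny, transform_lambda, vcv

__all__ = [
    "DesignSpec",
    "RegressionFit",
    "design_row",
    "fit_ols",
    "fit_gls",
    "fit_pgls_ml_lambda",
]


@dataclass
class DesignSpec:
    """Model formula, e.g. ``"y ~ x"`` or ``"y ~ x * C(group, Treatment('avian'))"``.

    Continuous predictors, categorical factors (treatment coding, with the
    reference level chosen in the formula) and interactions are supported
    through patsy.
    """

    formula: str

    def matrices(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, "DesignInfo"]:
        ymat, xmat = dmatrices(self.formula, data=table, return_type="dataframe")
        if ymat.shape[1] != 1:
            raise ValueError("response must be a single column")
        X = xmat.to_numpy(float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
                f"columns: {list(xmat.columns)})"
            )
        return ymat.to_numpy(float).ravel(), X, xmat.design_info


def design_row(design_info: "DesignInfo", values: dict) -> np.ndarray:
    """Design-matrix row for one target taxon's predictor values."""
    from patsy import build_design_matrices

    (m,) = build_design_matrices([design_info], pd.DataFrame([values]))
    return np.asarray(m, float).ravel()


@dataclass
class RegressionFit:
    """Fitted OLS/GLS/PGLS model with classical summaries.

    ``sigma2`` is the residual variance on the GLS-whitened scale with the
    unbiased n - p denominator; ``loglik`` is the maximised ML log-likelihood
    (which concentrates sigma2 with denominator n).  ``lam`` is Pagel's
    lambda: None for OLS, fixed or estimated for GLS/PGLS.  ``V`` is the
    (lambda-transformed) covariance structure actually used.
    """

    method: str
    params: pd.Series
    sigma2: float
    loglik: float
    resid: pd.Series
    fitted: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    r2_adj: float
    n: int
    p: int
    lam: float | None = None
    V: CovarianceStructure | None = None
    design_info: object = None
    xtvix_inv: np.ndarray | None = None  # (X' V^-1 X)^-1, reused for intervals
    X: np.ndarray | None = None  # design matrix on the fitting taxa
    taxa: list[str] = field(default_factory=list)

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    def summary(self) -> str:
        lines = [f"{self.method.upper()} fit: n={self.n}, p={self.p}"]
        if self.lam is not None:
            lines.append(f"lambda = {self.lam:.4f}")
        lines.append(f"sigma^2 = {self.sigma2:.6g}   logLik = {self.loglik:.4f}")
        lines.append(f"R^2 = {self.r2:.4f}   adj. R^2 = {self.r2_adj:.4f}")
        lines.append(f"{'term':<28}{'coef':>12}{'se':>12}{'t':>9}{'p':>10}")
        for term in self.params.index:
            lines.append(
                f"{term:<28}{self.params[term]:>12.5g}{self.se[term]:>12.5g}"
                f"{self.tvalues[term]:>9.3f}{self.pvalues[term]:>10.3g}"
            )
        return "\n".join(lines)


def _align(table: pd.DataFrame, cov: CovarianceStructure) -> pd.DataFrame:
    extra = [t for t in table.index if t not in set(cov.taxon_order)]
    missing = [t for t in cov.taxon_order if t not in set(table.index)]
    if extra or missing:
        raise ValueError(
            f"taxon mismatch between table and covariance structure; "
            f"in table only: {extra[:10]}, in V only: {missing[:10]}"
        )
    return table.loc[cov.taxon_order]


def _gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Whitened solve. Returns beta, rss, logdetV, xtvix_inv, resid."""
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is singular or not PD") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    rw = yw - Xw @ beta
    rss = float(rw @ rw)
    xtvix = Xw.T @ Xw
    xtvix_inv = np.linalg.inv(xtvix)
    resid = y - X @ beta
    return beta, rss, logdet, xtvix_inv, resid


def _loglik(n: int, rss: float, logdet: float) -> float:
    sigma2_ml = max(rss / n, 1e-300)
    return -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + n + logdet)


def _finish(
    method: str,
    table: pd.DataFrame,
    design: DesignSpec,
    cov: CovarianceStructure,
    lam: float | None,
) -> RegressionFit:
    table = _align(table, cov)
    y, X, dinfo = design.matrices(table)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    beta, rss, logdet, xtvix_inv, resid = _gls_core(y, X, cov.V)
    sigma2 = rss / (n - p)
    ll = _loglik(n, rss, logdet)
    se = np.sqrt(np.diag(xtvix_inv) * sigma2)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)

    # R^2 against the intercept-only model under the same covariance
    ones = np.ones((n, 1))
    _, tss, _, _, _ = _gls_core(y, ones, cov.V)
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if tss > 0 else math.nan

    names = list(dinfo.column_names)
    idx = pd.Index(table.index, name="taxon")
    return RegressionFit(
        method=method,
        params=pd.Series(beta, index=names),
        sigma2=sigma2,
        loglik=ll,
        resid=pd.Series(resid, index=idx),
        fitted=pd.Series(y - resid, index=idx),
        se=pd.Series(se, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        r2=r2,
        r2_adj=r2_adj,
        n=n,
        p=p,
        lam=lam,
        V=cov,
        design_info=dinfo,
        xtvix_inv=xtvix_inv,
        X=X,
        taxa=list(table.index),
    )


def fit_ols(table: pd.DataFrame, design: DesignSpec) -> RegressionFit:
    """Ordinary least squares (identity error covariance)."""
    taxa = list(table.index)
    cov = CovarianceStructure(np.eye(len(taxa)), taxa)
    fit = _finish("ols", table, design, cov, lam=None)
    fit.V = None
    return fit


def fit_gls(
    table: pd.DataFrame,
    design: DesignSpec,
    cov: CovarianceStructure,
    lam: float | None = None,
) -> RegressionFit:
    """GLS at a fixed covariance structure.

    When ``lam`` is given, ``cov`` is first lambda-transformed and the value
    recorded on the fit (so downstream predictions scale target covariances
    accordingly); otherwise ``cov`` is used as supplied.
    """
    if lam is not None:
        cov = transform_lambda(cov, lam)
    return _finish("gls", table, design, cov, lam=lam)


def fit_pgls_ml_lambda(
    table: pd.DataFrame,
    design: DesignSpec,
    tree: Phylogeny | CovarianceStructure,
    tol: float = 1e-8,
) -> RegressionFit:
    """PGLS with Pagel's lambda estimated by maximum likelihood on [0, 1].

    The profile log-likelihood (beta and sigma2 concentrated out) is
    maximised by bounded scalar search with explicit endpoint checks at 0 and
    1, which guards against boundary maxima.
    """
    base = vcv(tree) if isinstance(tree, Phylogeny) else tree
    aligned = _align(table, base.restrict([t for t in base.taxon_order if t in set(table.index)]))
    basesub = base.restrict(list(aligned.index))
    y, X, _ = DesignSpec(design.formula).matrices(aligned)
    n = len(y)

    Vd = np.diag(np.diag(basesub.V))

    def nll(lam: float) -> float:
        Vl = basesub.V * lam
        np.fill_diagonal(Vl, np.diag(basesub.V))
        _, rss, logdet, _, _ = _gls_core(y, X, Vl)
        return -_loglik(n, rss, logdet)

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": tol}
    )
    if not res.success:
        raise RuntimeError(f"lambda optimisation failed: {res}")
    candidates = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, float(res.x))]
    _, lam_hat = min(candidates, key=lambda c: c[0])
    fit = _finish("pgls", aligned, design, transform_lambda(basesub, lam_hat), lam=lam_hat)
    return fit
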