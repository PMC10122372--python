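"""Microbial relationship matrix and variance-component ("microbiability")
estimation.

The phenotype model is the linear mixed model

    y = X beta + m + e,      m ~ N(0, sigma2_m * M),    e ~ N(0, sigma2_e * I)

where M is the n x n microbial relationship matrix built from the genus
relative-abundance table A (samples x taxa):

    M_ij = (1/N) * sum_a (A_ia - Abar_a) (A_ja - Abar_a) / var_a

i.e. M = Z Z^T / N with each taxon column centered and scaled to unit
population variance.  With this standardization trace(M) = n and the mean
diagonal is 1, so the ratio sigma2_m / (sigma2_m + sigma2_e) is directly
interpretable as the fraction of phenotypic variance attributable to
microbial composition — the "microbiability", the microbiome analogue of
heritability.

Estimation is restricted maximum likelihood (REML).  M is eigendecomposed
once; y and X are rotated into the eigenbasis, after which the covariance
is diagonal for any variance ratio lambda = sigma2_m / sigma2_e and the
residual variance profiles out in closed form.  The REML criterion is then
a one-dimensional function of log(lambda), maximized by a coarse grid
bracket followed by bounded scalar refinement.  This is numerically stable
even though M is singular (its rows sum to zero by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .abundance import drop_zero_variance

logger = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Sample x sample microbial similarity matrix M = Z Z^T / N."""

    sample_ids: list[str]
    matrix: np.ndarray
    n_taxa: int
    taxon_means: pd.Series
    taxon_vars: pd.Series

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)

    def validate(self, atol: float = 1e-8) -> None:
        M = self.matrix
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("M is not symmetric")
        if not np.allclose(M.sum(axis=1), 0.0, atol=atol):
            raise ValueError("M rows do not sum to 0")
        n = M.shape[0]
        if abs(np.trace(M) - n) > max(atol, atol * n):
            raise ValueError("trace(M) != n")
        w = np.linalg.eigvalsh(M)
        if w.min() < -1e-8 * max(1.0, abs(w).max()):
            raise ValueError("M has a materially negative eigenvalue")


@dataclass
class VarianceComponents:
    """REML fit of y = X beta + m + e with cov(m) = sigma2_m * M."""

    sigma2_m: float
    sigma2_e: float
    beta: pd.Series
    loglik: float
    converged: bool
    n_iter: int
    boundary: bool
    lambda_hat: float
    n_samples: int
    n_taxa: int
    evaluations: int = 0
    notes: dict = field(default_factory=dict)

    @property
    def microbiability(self) -> float:
        """sigma2_m / (sigma2_m + sigma2_e): model-based phenotypic variance."""
        total = self.sigma2_m + self.sigma2_e
        if total <= 0:
            raise ValueError("total variance is zero; microbiability undefined")
        return self.sigma2_m / total

    def to_dict(self) -> dict:
        return {
            "sigma2_m": self.sigma2_m,
            "sigma2_e": self.sigma2_e,
            "microbiability": self.microbiability,
            "beta": self.beta.to_dict(),
            "reml_loglik": self.loglik,
            "converged": self.converged,
            "boundary": self.boundary,
            "lambda": self.lambda_hat,
            "n_samples": self.n_samples,
            "n_taxa": self.n_taxa,
            "variance_convention": "sigma2_p = sigma2_m + sigma2_e (model-based)",
        }


def build_relationship_matrix(table: pd.DataFrame) -> RelationshipMatrix:
    """Build M from a samples x taxa relative-abundance table.

    Taxa with zero variance across samples are excluded (and excluded from
    N).  Standardization uses the population (divide-by-n) variance so that
    trace(M) = n exactly.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples to build M")
    table = drop_zero_variance(table)
    if table.shape[1] == 0:
        raise ValueError("no taxon with nonzero variance; M is undefined")
    A = table.to_numpy(dtype=float)
    means = A.mean(axis=0)
    variances = A.var(axis=0)  # population variance
    Z = (A - means) / np.sqrt(variances)
    N = Z.shape[1]
    M = Z @ Z.T / N
    M = (M + M.T) / 2.0
    return RelationshipMatrix(
        sample_ids=list(table.index),
        matrix=M,
        n_taxa=N,
        taxon_means=pd.Series(means, index=table.columns),
        taxon_vars=pd.Series(variances, index=table.columns),
    )


def _profile_reml(log_lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> tuple[float, float, np.ndarray]:
    """REML log-likelihood profiled over sigma2_e at variance ratio
    lambda = exp(log_lam); returns (loglik, sigma2_e_hat, beta_hat)."""
    lam = np.exp(log_lam)
    n, p = Xt.shape
    w = 1.0 + lam * d
    wi = 1.0 / w
    XtW = Xt * wi[:, None]
    XtWX = XtW.T @ Xt
    XtWy = XtW.T @ yt
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.full(p, np.nan)
    r = yt - Xt @ beta
    rss_w = float(r @ (wi * r))
    if rss_w <= 0:
        rss_w = np.finfo(float).tiny
    sigma2_e = rss_w / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, np.nan, beta
    loglik = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma2_e)
        + np.sum(np.log(w))
        + logdet_xwx
        + (n - p)
    )
    return float(loglik), sigma2_e, beta


def fit_lmm_reml(
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None,
    M: RelationshipMatrix,
    bounds: tuple[float, float] = (1e-6, 1e6),
    tol: float = 1e-8,
    n_grid: int = 201,
) -> VarianceComponents:
    """REML estimation of (sigma2_m, sigma2_e) under V = sigma2_m M + sigma2_e I.

    Parameters
    ----------
    y : phenotype vector, aligned with ``M.sample_ids``.
    covariates : fixed-effect design WITHOUT the intercept (added here);
        None for an intercept-only model.
    bounds : search interval for lambda = sigma2_m / sigma2_e.
    tol : convergence tolerance on log(lambda).

    The profile criterion is evaluated on an ``n_grid``-point log-spaced
    grid over ``bounds`` to bracket the optimum, then refined by bounded
    scalar minimization.  Solutions at the bounds are flagged
    ``boundary=True`` (lambda at the lower bound means "no detectable
    microbial variance", at the upper "no residual variance").
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n != M.n_samples:
        raise ValueError("y and M dimensions disagree")
    if covariates is None:
        X = np.ones((n, 1))
        names = ["intercept"]
    else:
        C = pd.DataFrame(covariates)
        X = np.column_stack([np.ones(n), C.to_numpy(dtype=float)])
        names = ["intercept"] + [str(c) for c in C.columns]
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("covariate design matrix is rank-deficient")
    if n <= p + 1:
        raise ValueError("too few samples for the fixed-effect design")

    # degenerate input: y in the column space of X -> no stochastic variance
    beta_ols, res_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_ols = float(np.sum((y - X @ beta_ols) ** 2))
    scale = max(1.0, float(y @ y))
    if rss_ols <= 1e-12 * scale:
        return VarianceComponents(
            sigma2_m=0.0,
            sigma2_e=0.0,
            beta=pd.Series(beta_ols, index=names),
            loglik=np.inf,
            converged=True,
            n_iter=0,
            boundary=True,
            lambda_hat=bounds[0],
            n_samples=n,
            n_taxa=M.n_taxa,
            notes={"degenerate": "y lies in the fixed-effect column space"},
        )

    d, U = np.linalg.eigh(M.matrix)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    evals = {"count": 0}

    def objective(log_lam: float) -> float:
        evals["count"] += 1
        ll, _, _ = _profile_reml(log_lam, d, yt, Xt)
        return -ll

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    grid_ll = np.array([-objective(g) for g in grid])
    if not np.isfinite(grid_ll).any():
        raise RuntimeError("REML likelihood non-finite over the whole grid")
    k = int(np.argmax(grid_ll))
    left = grid[max(k - 1, 0)]
    right = grid[min(k + 1, n_grid - 1)]
    if k in (0, n_grid - 1):
        best_log_lam = grid[k]
        n_iter = 0
    else:
        res = minimize_scalar(
            objective,
            bounds=(left, right),
            method="bounded",
            options={"xatol": tol, "maxiter": 500},
        )
        if not res.success:
            raise RuntimeError(f"REML refinement failed: {res.message}; "
                               f"{evals['count']} evaluations")
        best_log_lam = float(res.x)
        n_iter = int(res.nfev)

    ll, sigma2_e, beta = _profile_reml(best_log_lam, d, yt, Xt)
    if not np.isfinite(ll):
        raise RuntimeError("REML likelihood non-finite at the optimum")
    lam = float(np.exp(best_log_lam))
    boundary = lam <= bounds[0] * 1.01 or lam >= bounds[1] / 1.01
    sigma2_m = lam * sigma2_e
    return VarianceComponents(
        sigma2_m=sigma2_m,
        sigma2_e=sigma2_e,
        beta=pd.Series(beta, index=names),
        loglik=ll,
        converged=True,
        n_iter=n_iter,
        boundary=boundary,
        lambda_hat=lam,
        n_samples=n,
        n_taxa=M.n_taxa,
        evaluations=evals["count"],
    )


def profile_reml_loglik(
    lam: float, y: np.ndarray, X: np.ndarray, M: RelationshipMatrix
) -> float:
    """Profile REML log-likelihood at a given variance ratio lambda.

    Exposed for grid-search cross-checks; shares no optimizer state with
    :func:`fit_lmm_reml`.
    """
    d, U = np.linalg.eigh(M.matrix)
    d = np.clip(d, 0.0, None)
    ll, _, _ = _profile_reml(np.log(lam), d, U.T @ np.asarray(y, float), U.T @ X)
    return ll


def microbiability(vc: VarianceComponents) -> float:
    """The microbiability ratio sigma2_m / (sigma2_m + sigma2_e)."""
    return vc.microbiability


def bootstrap_microbiability(
    y: np.ndarray,
    covariates: pd.DataFrame | None,
    M: RelationshipMatrix,
    vc: VarianceComponents,
    n_boot: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Seeded parametric bootstrap of the microbiability estimate.

    Resimulates y from the fitted model and refits; returns the bootstrap
    estimates (no SE is attached to the point estimate by default).
    """
    rng = np.random.default_rng(seed)
    n = M.n_samples
    d, U = np.linalg.eigh(M.matrix)
    d = np.clip(d, 0.0, None)
    L = U * np.sqrt(d)
    if covariates is None:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), pd.DataFrame(covariates).to_numpy(float)])
    mean = X @ vc.beta.to_numpy()
    out = np.empty(n_boot)
    for b in range(n_boot):
        m = np.sqrt(vc.sigma2_m) * (L @ rng.standard_normal(n))
        e = np.sqrt(vc.sigma2_e) * rng.standard_normal(n)
        fit = fit_lmm_reml(mean + m + e, covariates, M)
        out[b] = fit.microbiability
    return out
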