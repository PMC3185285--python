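"""Phylogenetic generalized least squares under Brownian motion.

Implements the bivariate trait model with Pagel's lambda scaling, in two mean
structures:

``constant``
    each trait has a single ancestral mean (constant-variance random walk);
``directional``
    each trait's mean drifts linearly with total root-to-tip path length
    (directional random walk; identifiable only on non-ultrametric trees).

On top of the fits sit the two likelihood-ratio tests used to screen each
gene:

* the **lambda test** (is any phylogenetic signal present? free lambda vs
  lambda = 0), and
* the **covariance test** (is the between-trait covariance non-zero, with the
  tree taken at face value, lambda = 1) — when lambda is 1 the ML correlation
  equals the through-origin correlation of independent contrasts.

``route_correlation_test`` reproduces the decision procedure: if the lambda
test is not significant, an ordinary Pearson correlation is reported (R^2
column); otherwise the phylogenetically corrected covariance test is (BT
column).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

from .phylo import Phylogeny, apply_lambda

__all__ = [
    "PGLSError",
    "GLSFit",
    "CorrelationResult",
    "LambdaTestResult",
    "CovarianceTestResult",
    "ScreenResult",
    "gls_fit",
    "lambda_test",
    "covariance_test",
    "pearson_test",
    "route_correlation_test",
    "screen_table",
]

_LN_2PI = math.log(2.0 * math.pi)
_ULTRAMETRIC_TOL = 1e-9


class PGLSError(ValueError):
    """Raised for unusable designs or degenerate trait data."""


@dataclass(frozen=True)
class GLSFit:
    """A fitted (possibly bivariate) phylogenetic GLS model."""

    model: str                 # "constant" | "directional"
    lam: float                 # Pagel's lambda used for the fit
    lam_free: bool             # whether lam was profiled over [0, 1]
    coef: pd.DataFrame         # design columns x traits
    Sigma: np.ndarray          # ML trait covariance (p x p)
    loglik: float
    n: int
    trait_names: tuple

    @property
    def rho(self) -> float:
        if self.Sigma.shape != (2, 2):
            raise PGLSError("rho is defined for bivariate fits only")
        denom = math.sqrt(self.Sigma[0, 0] * self.Sigma[1, 1])
        if denom == 0.0:
            raise PGLSError("degenerate trait covariance; rho undefined")
        return float(self.Sigma[0, 1] / denom)


@dataclass(frozen=True)
class CorrelationResult:
    method: str                # "pearson" | "phylogenetic"
    r: float
    beta: float | None
    statistic: float
    p: float
    df: int | None


@dataclass(frozen=True)
class LambdaTestResult:
    lr: float
    p: float
    lambda_hat: float
    model: str
    fit_free: GLSFit
    fit_zero: GLSFit


@dataclass(frozen=True)
class CovarianceTestResult:
    lr: float
    p: float
    rho_hat: float
    fit_free: GLSFit | None


@dataclass(frozen=True)
class ScreenResult:
    """One row of the per-gene screen (the Tables 1-4 shape): lambda test,
    then exactly one of the Pearson (R^2) or phylogenetic (BT) branches."""

    gene: str
    lr_lambda: float
    p_lambda: float
    lambda_hat: float
    model: str
    route: str                 # "pearson" | "phylogenetic"
    bt_p: float | None
    r2: float | None
    r2_p: float | None

    @property
    def final_p(self) -> float:
        return self.bt_p if self.route == "phylogenetic" else self.r2_p


# ---------------------------------------------------------------------------
# core likelihood machinery
# ---------------------------------------------------------------------------


def _as_matrix(Y) -> pd.DataFrame:
    if isinstance(Y, pd.Series):
        Y = Y.to_frame()
    if not isinstance(Y, pd.DataFrame):
        raise PGLSError("Y must be a pandas Series or DataFrame indexed by tip")
    if Y.shape[1] not in (1, 2):
        raise PGLSError("only univariate or bivariate fits are supported")
    if Y.shape[0] < 3:
        raise PGLSError("need at least 3 species")
    if Y.isna().any().any():
        bad = Y.index[Y.isna().any(axis=1)].tolist()
        raise PGLSError(f"missing trait values for species: {bad}")
    return Y.astype(float)


def _design(tree: Phylogeny, index: pd.Index, model: str) -> np.ndarray:
    n = len(index)
    if model == "constant":
        return np.ones((n, 1))
    if model == "directional":
        rtl = tree.root_to_tip_lengths().loc[index].to_numpy()
        if rtl.max() - rtl.min() < _ULTRAMETRIC_TOL:
            raise PGLSError(
                "directional parameter unidentifiable: tree is ultrametric"
            )
        return np.column_stack([np.ones(n), rtl])
    raise PGLSError(f"unknown model kind: {model!r}")


def _fit_given_V(Y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Closed-form GLS estimates and matrix-normal log-likelihood for a
    fixed tip covariance V.  Returns (B, Sigma, loglik)."""
    n, p = Y.shape
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise PGLSError(f"singular tip covariance: {exc}") from exc
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ViX = linalg.cho_solve(cf, X)
    ViY = linalg.cho_solve(cf, Y)
    A = X.T @ ViX
    try:
        B = np.linalg.solve(A, X.T @ ViY)
    except np.linalg.LinAlgError as exc:
        raise PGLSError(f"singular design: {exc}") from exc
    E = Y - X @ B
    S = E.T @ linalg.cho_solve(cf, E) / n
    sign, logdet_S = np.linalg.slogdet(S)
    scale = float(np.trace(S)) / p
    if sign <= 0 or (scale > 0 and logdet_S < p * math.log(scale) - 60.0):
        raise PGLSError(
            "degenerate trait covariance (constant trait or exactly "
            "collinear traits)"
        )
    loglik = -0.5 * (n * p * _LN_2PI + p * logdet_V + n * logdet_S + n * p)
    return B, S, float(loglik)


def _profile_lambda(Y: np.ndarray, X: np.ndarray, V0: np.ndarray) -> float:
    """Maximize the profile log-likelihood over lambda in [0, 1]:
    21-point grid scan, then golden-section refinement (ties -> smaller)."""

    def nll(lam: float) -> float:
        try:
            return -_fit_given_V(Y, X, apply_lambda_np(V0, lam))[2]
        except PGLSError:
            return np.inf

    grid = np.linspace(0.0, 1.0, 21)
    vals = np.array([nll(g) for g in grid])
    if not np.isfinite(vals).any():
        raise PGLSError(
            "degenerate trait covariance (constant trait or exactly "
            "collinear traits)"
        )
    k = int(np.argmin(vals))  # first minimum -> smaller lambda on ties
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi - lo < 1e-12:
        return float(grid[k])
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
    )
    lam = float(res.x)
    if nll(lam) > vals[k] + 1e-12:
        lam = float(grid[k])
    return min(max(lam, 0.0), 1.0)


def apply_lambda_np(V0: np.ndarray, lam: float) -> np.ndarray:
    A = V0 * lam
    np.fill_diagonal(A, np.diag(V0))
    return A


# ---------------------------------------------------------------------------
# public fits and tests
# ---------------------------------------------------------------------------


def gls_fit(Y, tree: Phylogeny, lam="free", model: str = "constant") -> GLSFit:
    """Fit the phylogenetic GLS model.

    Parameters
    ----------
    Y : DataFrame (species x 1-or-2 traits), index = tip labels
    lam : float in [0, 1], or "free" to maximize the profile likelihood
    model : "constant", "directional", or "auto" (fit both, keep the higher
        log-likelihood; falls back to constant on ultrametric trees)
    """
    Yf = _as_matrix(Y)
    tips = set(tree.tip_labels)
    if set(Yf.index) != tips:
        raise PGLSError(
            "trait table index must match the tree's tips exactly; "
            f"difference: {set(Yf.index) ^ tips}"
        )
    if model == "auto":
        fits = [gls_fit(Yf, tree, lam=lam, model="constant")]
        try:
            fits.append(gls_fit(Yf, tree, lam=lam, model="directional"))
        except PGLSError:
            pass
        return max(fits, key=lambda f: f.loglik)

    V0 = tree.bm_covariance().loc[Yf.index, Yf.index].to_numpy()
    X = _design(tree, Yf.index, model)
    Ynp = Yf.to_numpy()
    if lam == "free":
        lam_hat = _profile_lambda(Ynp, X, V0)
        lam_free = True
    else:
        lam_hat = float(lam)
        if not 0.0 <= lam_hat <= 1.0:
            raise PGLSError(f"lambda must lie in [0, 1], got {lam_hat}")
        lam_free = False
    B, S, ll = _fit_given_V(Ynp, X, apply_lambda_np(V0, lam_hat))
    design_names = (
        ["intercept"] if model == "constant" else ["intercept", "root_to_tip"]
    )
    return GLSFit(
        model=model,
        lam=lam_hat,
        lam_free=lam_free,
        coef=pd.DataFrame(B, index=design_names, columns=Yf.columns),
        Sigma=S,
        loglik=ll,
        n=Yf.shape[0],
        trait_names=tuple(Yf.columns),
    )


def lambda_test(Y, tree: Phylogeny, model: str = "auto") -> LambdaTestResult:
    """Likelihood-ratio test of phylogenetic signal: lambda free vs
    lambda = 0, chi-square with 1 df.  For bivariate Y a single lambda is
    shared by both traits."""
    Yf = _as_matrix(Y)
    fit_free = gls_fit(Yf, tree, lam="free", model=model)
    fit_zero = gls_fit(Yf, tree, lam=0.0, model=fit_free.model)
    lr = max(0.0, 2.0 * (fit_free.loglik - fit_zero.loglik))
    p = float(sps.chi2.sf(lr, df=1))
    return LambdaTestResult(
        lr=lr,
        p=p,
        lambda_hat=fit_free.lam,
        model=fit_free.model,
        fit_free=fit_free,
        fit_zero=fit_zero,
    )


def covariance_test(
    Y, tree: Phylogeny, model: str = "constant"
) -> CovarianceTestResult:
    """Likelihood-ratio test of the between-trait covariance with the tree
    taken at face value (lambda = 1): Sigma free vs Sigma12 = 0, chi-square
    with 1 df."""
    Yf = _as_matrix(Y)
    if Yf.shape[1] != 2:
        raise PGLSError("covariance_test needs exactly 2 traits")
    try:
        fit_free = gls_fit(Yf, tree, lam=1.0, model=model)
    except PGLSError as exc:
        if "collinear" in str(exc) or "constant" in str(exc):
            warnings.warn(
                "traits are exactly collinear; likelihood ratio capped at "
                "infinity",
                RuntimeWarning,
                stacklevel=2,
            )
            return CovarianceTestResult(
                lr=math.inf, p=0.0, rho_hat=1.0, fit_free=None
            )
        raise
    ll0 = 0.0
    for col in Yf.columns:
        ll0 += gls_fit(Yf[[col]], tree, lam=1.0, model=model).loglik
    lr = max(0.0, 2.0 * (fit_free.loglik - ll0))
    p = float(sps.chi2.sf(lr, df=1))
    return CovarianceTestResult(lr=lr, p=p, rho_hat=fit_free.rho, fit_free=fit_free)


def pearson_test(x, y) -> CorrelationResult:
    """Ordinary (non-phylogenetic) Pearson correlation with OLS slope and a
    two-sided t test on n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PGLSError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise PGLSError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise PGLSError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    beta = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * math.sqrt(df) / math.sqrt(max(1.0 - r * r, 1e-300))
    return CorrelationResult(
        method="pearson", r=r, beta=beta, statistic=float(t),
        p=float(res.pvalue), df=df,
    )


def route_correlation_test(
    Y,
    tree: Phylogeny,
    alpha: float = 0.05,
    model: str = "auto",
    gene: str = "",
) -> ScreenResult:
    """The per-gene decision procedure.

    Run the lambda test; if its p-value is >= alpha, phylogenetic correction
    is unnecessary and the plain Pearson correlation is reported (R^2 and its
    p); if p < alpha (strict), the covariance test with lambda = 1 is
    reported instead (BT p).  Exactly one branch is populated.
    """
    Yf = _as_matrix(Y)
    if Yf.shape[1] != 2:
        raise PGLSError("route_correlation_test needs exactly 2 traits")
    lt = lambda_test(Yf, tree, model=model)
    if lt.p < alpha:
        ct = covariance_test(Yf, tree, model="constant")
        return ScreenResult(
            gene=gene, lr_lambda=lt.lr, p_lambda=lt.p,
            lambda_hat=lt.lambda_hat, model=lt.model,
            route="phylogenetic", bt_p=ct.p, r2=None, r2_p=None,
        )
    pt = pearson_test(Yf.iloc[:, 0].to_numpy(), Yf.iloc[:, 1].to_numpy())
    return ScreenResult(
        gene=gene, lr_lambda=lt.lr, p_lambda=lt.p,
        lambda_hat=lt.lambda_hat, model=lt.model,
        route="pearson", bt_p=None, r2=pt.r**2, r2_p=pt.p,
    )


def screen_table(results: list[ScreenResult]) -> pd.DataFrame:
    """Assemble screen results into the Tables 1-4 column layout
    (gene, LR for lambda, its p, BT p, R^2, R^2 p; NA where the branch was
    not taken)."""
    rows = []
    for r in results:
        rows.append(
            {
                "Gene": r.gene,
                "LR (for lambda)": r.lr_lambda,
                "p-value": r.p_lambda,
                "BT p-value": r.bt_p,
                "R^2": r.r2,
                "R^2 p-value": r.r2_p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Gene", "LR (for lambda)", "p-value",
            "BT p-value", "R^2", "R^2 p-value",
        ],
    )
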