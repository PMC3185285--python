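"""Resampling tests, exact enrichment, Box-Cox transforms, and the
contrast-based multiple regression.

The contrast regression is the phylogeny-aware analogue of an ANCOVA:
species-level variables are (optionally) Box-Cox transformed, converted to
Felsenstein independent contrasts per gene, stacked across genes, and fit by
ordinary least squares through the origin with set-specific effects
('gene set' = focal piRNA-pathway genes vs matched controls) and a
TE x gene-set interaction; each effect gets a Type-III F test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps
import statsmodels.api as sm

from .phylo import Phylogeny

__all__ = [
    "StatsError",
    "BootstrapResult",
    "ContrastRegressionResult",
    "fisher_exact_2tail",
    "bootstrap_mean_ci",
    "bootstrap_mean_diff_test",
    "slope_ttest",
    "shift_positive",
    "boxcox_fit_transform",
    "contrast_regression",
    "format_regression_table",
]


class StatsError(ValueError):
    """Invalid inputs to a statistical routine."""


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    p: float            # one-sided: fraction of resampled means <= 0
    n_boot: int
    seed: int


@dataclass(frozen=True)
class ContrastRegressionResult:
    table: pd.DataFrame          # Effect / num df / den df / F / p
    design: pd.DataFrame         # stacked, positivized contrast rows
    powers: dict                 # Box-Cox power per transformed variable
    shifts: dict                 # positivity shift per transformed variable
    model: object                # statsmodels OLS results


# ---------------------------------------------------------------------------
# enrichment and simple tests
# ---------------------------------------------------------------------------


def fisher_exact_2tail(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]], by the
    minimum-likelihood rule (sum over tables with fixed margins whose
    probability does not exceed the observed table's)."""
    for v in (a, b, c, d):
        if int(v) != v or v < 0:
            raise StatsError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b == 0 or c + d == 0:
        raise StatsError("each row of the 2x2 table must have a positive margin")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bootstrap_mean_ci(values, n_boot: int = 10000, seed: int = 0) -> BootstrapResult:
    """Percentile 95% CI of the mean from n_boot bootstrap resamples.
    Deterministic given (seed, n_boot)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise StatsError("need at least 3 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    p = (int(np.count_nonzero(means <= 0.0)) + 1) / (n_boot + 1)
    return BootstrapResult(
        estimate=float(x.mean()), ci_low=float(lo), ci_high=float(hi),
        p=float(p), n_boot=n_boot, seed=seed,
    )


def bootstrap_mean_diff_test(
    control, focal, n_boot: int = 10000, seed: int = 0
) -> float:
    """One-sided bootstrap comparison of group means: both groups are
    independently resampled with replacement n_boot times and
    p = (#{mean_control <= mean_focal} + 1) / (n_boot + 1)."""
    c = np.asarray(control, dtype=float)
    f = np.asarray(focal, dtype=float)
    if c.size < 3 or f.size < 3:
        raise StatsError("need at least 3 values per group")
    rng = np.random.default_rng(seed)
    mc = c[rng.integers(0, c.size, size=(n_boot, c.size))].mean(axis=1)
    mf = f[rng.integers(0, f.size, size=(n_boot, f.size))].mean(axis=1)
    return float((int(np.count_nonzero(mc <= mf)) + 1) / (n_boot + 1))


def slope_ttest(betas_a, betas_b, welch: bool = False) -> tuple[float, float]:
    """Two-sample two-sided t test on per-gene regression slopes
    (pooled-variance by default; Welch optional)."""
    a = np.asarray(betas_a, dtype=float)
    b = np.asarray(betas_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("need at least 2 slopes per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0 and a.mean() == b.mean():
        raise StatsError("zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------


def shift_positive(values) -> tuple[np.ndarray, float]:
    """Shift a vector by (1 - min) if any value is non-positive; returns
    (shifted values, shift applied)."""
    x = np.asarray(values, dtype=float)
    shift = 0.0
    if x.min() <= 0.0:
        shift = 1.0 - x.min()
        x = x + shift
    return x, shift


def boxcox_fit_transform(
    values, bounds: tuple[float, float] = (-3.0, 3.0)
) -> tuple[float, np.ndarray]:
    """Box-Cox transform with the power chosen by maximizing the profile
    log-likelihood over *bounds*; y -> (y^p - 1)/p, or ln y at p = 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise StatsError("need at least 3 values")
    if np.any(x <= 0.0):
        raise StatsError("Box-Cox requires strictly positive values "
                         "(apply shift_positive first)")
    if np.ptp(x) == 0.0:
        return 1.0, x - 1.0

    def nll(p: float) -> float:
        return -sps.boxcox_llf(p, x)

    grid = np.linspace(bounds[0], bounds[1], 25)
    k = int(np.argmin([nll(g) for g in grid]))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
    )
    power = float(res.x)
    return power, special.boxcox(x, power)


# ---------------------------------------------------------------------------
# contrast multiple regression
# ---------------------------------------------------------------------------

_EFFECT_LABEL = {"te": "TE", "gc3": "GC3", "length": "Length", "omega": "omega",
                 "enc": "ENC"}


def _label(name: str) -> str:
    return _EFFECT_LABEL.get(name, name)


def contrast_regression(
    panel: pd.DataFrame,
    te: pd.Series,
    tree: Phylogeny,
    response: str = "omega",
    covariates: tuple = ("gc3", "length"),
    boxcox: bool = True,
    positivize: bool = True,
) -> ContrastRegressionResult:
    """Multiple regression of response contrasts on TE contrasts, gene-set
    membership and covariate contrasts.

    Parameters
    ----------
    panel : long-format DataFrame with columns ``gene``, ``set`` (values
        "piRNA"/"control"), ``species``, the response column and any
        per-gene covariate columns.
    te : per-species TE abundance (Mb), indexed by tip label.
    tree : the phylogeny on which contrasts are taken.
    covariates : per-gene species-level covariate columns to include
        (besides TE, which is always included together with the
        TE x gene-set interaction).

    Species-level variables are Box-Cox transformed (shifted positive first
    where needed) before contrasts are taken; each stacked row is sign-flipped
    so its TE contrast is non-negative (through-origin convention).  The
    design has no global intercept: effects are TE, the two gene-set levels,
    TE x gene set, then the covariates, each with a Type-III F test against
    the OLS residual.
    """
    required = {"gene", "set", "species", response, *covariates}
    missing = required - set(panel.columns)
    if missing:
        raise StatsError(f"panel is missing columns: {sorted(missing)}")
    sets = set(panel["set"])
    if not sets <= {"piRNA", "control"}:
        raise StatsError(f"unknown gene-set labels: {sets - {'piRNA', 'control'}}")

    tips = tree.tip_labels
    powers: dict[str, float] = {}
    shifts: dict[str, float] = {}

    def transform(name: str, vec: pd.Series) -> pd.Series:
        if not boxcox:
            return vec
        shifted, _ = shift_positive(vec.to_numpy())
        return pd.Series(
            special.boxcox(shifted, powers[name]), index=vec.index
        )

    if boxcox:
        # one power per variable, fitted on the pooled species-level values
        for name in (response, "te", *covariates):
            pooled = (
                te.loc[tips].to_numpy()
                if name == "te"
                else panel[name].to_numpy()
            )
            shifted, shift = shift_positive(pooled)
            powers[name], _ = boxcox_fit_transform(shifted)
            shifts[name] = shift

        def transform(name: str, vec: pd.Series) -> pd.Series:  # noqa: F811
            x = vec.to_numpy(dtype=float) + shifts[name]
            if np.any(x <= 0.0):
                raise StatsError(
                    f"{name}: values non-positive even after the pooled shift"
                )
            return pd.Series(special.boxcox(x, powers[name]), index=vec.index)

    te_t = transform("te", te.loc[tips]) if boxcox else te.loc[tips]
    te_contr = tree.independent_contrasts(te_t)
    node_ids = te_contr.node_ids
    te_c = te_contr.values

    rows = []
    for gene, sub in panel.groupby("gene", sort=True):
        sub = sub.set_index("species")
        missing_sp = set(tips) - set(sub.index)
        if missing_sp:
            raise StatsError(
                f"gene {gene!r}: missing species {sorted(missing_sp)}"
            )
        gene_set = sub["set"].iloc[0]
        block = {"gene": gene, "set": gene_set}
        vecs = {"resp_c": tree.independent_contrasts(
            transform(response, sub[response]) if boxcox else sub[response]
        ).values}
        for cov in covariates:
            vecs[f"{cov}_c"] = tree.independent_contrasts(
                transform(cov, sub[cov]) if boxcox else sub[cov]
            ).values
        for i, node in enumerate(node_ids):
            row = {"gene": gene, "set": gene_set, "node": node, "te_c": te_c[i]}
            for k, v in vecs.items():
                row[k] = v[i]
            rows.append(row)
    design = pd.DataFrame(rows)

    if positivize:
        sgn = np.where(design["te_c"] < 0, -1.0, 1.0)
        for col in ["te_c", "resp_c"] + [f"{c}_c" for c in covariates]:
            design[col] = design[col] * sgn

    design["is_pirna"] = (design["set"] == "piRNA").astype(float)
    design["is_control"] = (design["set"] == "control").astype(float)
    design["te_x_pirna"] = design["te_c"] * design["is_pirna"]

    effects: list[tuple[str, list[str]]] = [("TE", ["te_c"])]
    if len(sets) == 2:
        effects.append(("Gene Set", ["is_pirna", "is_control"]))
        effects.append(("TE X Gene Set", ["te_x_pirna"]))
    for cov in covariates:
        effects.append((_label(cov), [f"{cov}_c"]))

    cols = [c for _, group in effects for c in group]
    X = design[cols].to_numpy(dtype=float)
    y = design["resp_c"].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # a column is implicated if dropping it does not reduce the rank
        collinear = [
            col
            for j, col in enumerate(cols)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise StatsError(
            f"rank-deficient design; collinear columns: {collinear or cols}"
        )
    fit = sm.OLS(y, X).fit()
    den_df = int(fit.df_resid)
    out = []
    for name, group in effects:
        R = np.zeros((len(group), X.shape[1]))
        for r, col in enumerate(group):
            R[r, cols.index(col)] = 1.0
        ft = fit.f_test(R)
        out.append(
            {
                "Effect": name,
                "num_df": len(group),
                "den_df": den_df,
                "F": float(ft.fvalue),
                "p": float(ft.pvalue),
            }
        )
    table = pd.DataFrame(out, columns=["Effect", "num_df", "den_df", "F", "p"])
    return ContrastRegressionResult(
        table=table, design=design, powers=powers, shifts=shifts, model=fit
    )


def format_regression_table(table: pd.DataFrame) -> pd.DataFrame:
    """Rename columns to the printed layout: Effect / DF / DF / F Value /
    Pr > F (numerator df first, denominator df second)."""
    out = table.copy()
    out.columns = ["Effect", "DF", "DF", "F Value", "Pr > F"]
    return out
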