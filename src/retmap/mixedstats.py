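"""Random-intercept linear mixed models, BIC all-subsets selection, Spearman.

The model is y = X beta + Z b + e with one random intercept per patient,
b ~ N(0, sigma_b^2) and e ~ N(0, sigma_e^2).  Writing V0 = I + lambda Z Z',
lambda = sigma_b^2 / sigma_e^2, the likelihood is maximised by profiling:
for fixed lambda, beta is the GLS solution and sigma_e^2 has a closed form;
the remaining 1-D problem in log(lambda) is solved numerically on
[1e-8, 1e8] to a tolerance of 1e-10.  The restricted likelihood adds the
-1/2 log|X' V0^-1 X| adjustment.  Because Z Z' is block diagonal in the
patient, everything reduces to per-patient sufficient statistics
(group sums of X and y), which also makes exhaustive all-subsets model
selection cheap: every candidate submodel reuses slices of the global
model's cross-products.

Confidence intervals and p-values for fixed effects are Wald
(normal-approximation), conditional on the estimated variance components.
Analyses are exploratory: raw p-values are reported, with no multiplicity
correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

#: candidate fixed-effect terms of the structure-function analysis
CANDIDATE_TERMS: tuple[str, ...] = (
    "device", "run", "eccentricity", "age", "EZ", "ONL", "GCL", "RNFL",
)
#: interaction terms analysed univariately (with their main effects)
INTERACTION_TERMS: tuple[str, ...] = (
    "EZ:eccentricity", "ONL:eccentricity", "age:EZ", "EZ:ONL",
)

_LOG_LAMBDA_BOUNDS = (np.log(1e-8), np.log(1e8))
_LAMBDA_XATOL = 1e-10


class RankDeficientDesign(ValueError):
    pass


class NoGroupingVariance(UserWarning):
    """Raised as a warning when the data cannot identify sigma_b."""


@dataclass(frozen=True)
class LMMSpec:
    """Model specification: fixed terms, grouping and estimation method."""

    fixed_terms: tuple[str, ...]
    method: Literal["ML", "REML"] = "ML"
    response: str = "db"
    group: str = "eye_id"

    def __post_init__(self):
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))


@dataclass
class LMMFit:
    """Fitted random-intercept LMM."""

    terms: tuple[str, ...]            # including "(Intercept)"
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    sigma_b: float
    sigma_e: float
    loglik: float
    method: str
    n_obs: int
    n_groups: int
    k_params: int                     # parameters counted in BIC
    converged: bool = True

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k_params * np.log(self.n_obs)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_values,
            },
            index=list(self.terms),
        )


# ---------------------------------------------------------------------------
# Design matrix encoding
# ---------------------------------------------------------------------------


def _encode_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == "device":
        return (df["device"].astype(str) == "MAIA").to_numpy(float)
    if term == "run":
        return (df["run"].astype(int) == 2).to_numpy(float)
    if ":" in term:
        a, b = term.split(":")
        return _encode_column(df, a) * _encode_column(df, b)
    return df[term].to_numpy(float)


def _model_columns(term: str) -> list[str]:
    """Raw data columns a term depends on (for row-wise NaN dropping)."""
    if term in ("device", "run"):
        return [term]
    if ":" in term:
        return sum((_model_columns(t) for t in term.split(":")), [])
    return [term]


def build_design(
    data: pd.DataFrame, spec: LMMSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """(X, y, integer group codes, term names); drops incomplete rows."""
    needed = {spec.response, spec.group}
    for t in spec.fixed_terms:
        needed.update(_model_columns(t))
    sub = data.dropna(subset=sorted(needed))
    y = sub[spec.response].to_numpy(float)
    cols = [np.ones(len(sub))]
    for t in spec.fixed_terms:
        cols.append(_encode_column(sub, t))
    X = np.column_stack(cols)
    groups = pd.Categorical(sub[spec.group]).codes.astype(int)
    return X, y, groups, ("(Intercept)", *spec.fixed_terms)


# ---------------------------------------------------------------------------
# Profiled likelihood on per-group sufficient statistics
# ---------------------------------------------------------------------------


@dataclass
class _SuffStats:
    XtX: np.ndarray   # (p, p)
    Xty: np.ndarray   # (p,)
    yty: float
    Sx: np.ndarray    # (m, p) per-group column sums of X
    Sy: np.ndarray    # (m,)  per-group sums of y
    ng: np.ndarray    # (m,)  group sizes
    n: int
    p: int

    @classmethod
    def from_arrays(cls, X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> "_SuffStats":
        m = int(groups.max()) + 1
        Sx = np.zeros((m, X.shape[1]))
        np.add.at(Sx, groups, X)
        Sy = np.bincount(groups, weights=y, minlength=m)
        ng = np.bincount(groups, minlength=m).astype(float)
        return cls(
            XtX=X.T @ X, Xty=X.T @ y, yty=float(y @ y),
            Sx=Sx, Sy=Sy, ng=ng, n=len(y), p=X.shape[1],
        )

    def subset(self, idx: Sequence[int]) -> "_SuffStats":
        idx = np.asarray(idx, int)
        return _SuffStats(
            XtX=self.XtX[np.ix_(idx, idx)], Xty=self.Xty[idx], yty=self.yty,
            Sx=self.Sx[:, idx], Sy=self.Sy, ng=self.ng, n=self.n, p=len(idx),
        )


def _profile_eval(log_lambda: float, s: _SuffStats, reml: bool):
    """-2 log(likelihood) profiled over beta and sigma_e^2 at fixed lambda."""
    lam = np.exp(log_lambda)
    c = lam / (1.0 + lam * s.ng)
    A = s.XtX - (s.Sx * c[:, None]).T @ s.Sx
    b = s.Xty - s.Sx.T @ (c * s.Sy)
    q = s.yty - float((c * s.Sy) @ s.Sy)
    try:
        L = cho_factor(A, lower=True)
    except np.linalg.LinAlgError as err:
        raise RankDeficientDesign("singular GLS system") from err
    beta = cho_solve(L, b)
    rss = max(q - float(b @ beta), 1e-300)
    ld_v0 = float(np.sum(np.log1p(lam * s.ng)))
    n, p = s.n, s.p
    if reml:
        sigma_e2 = rss / (n - p)
        ld_a = 2.0 * float(np.sum(np.log(np.diag(L[0]))))
        crit = (n - p) * np.log(2 * np.pi * sigma_e2) + ld_v0 + ld_a + (n - p)
    else:
        sigma_e2 = rss / n
        crit = n * np.log(2 * np.pi * sigma_e2) + ld_v0 + n
    return crit, beta, sigma_e2, A, L


def _fit_from_stats(
    s: _SuffStats, reml: bool, terms: tuple[str, ...], n_groups: int,
    bic_count_variance: bool = True,
) -> LMMFit:
    if np.linalg.matrix_rank(s.XtX) < s.p:
        raise RankDeficientDesign(
            f"fixed-effect design of rank < {s.p}: terms {terms}"
        )

    res = optimize.minimize_scalar(
        lambda ll: _profile_eval(ll, s, reml)[0],
        bounds=_LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": _LAMBDA_XATOL},
    )
    # the boundary lambda -> 0 (no grouping variance) is a legitimate optimum
    cands = [res.x, _LOG_LAMBDA_BOUNDS[0]]
    vals = [_profile_eval(ll, s, reml)[0] for ll in cands]
    log_lambda = cands[int(np.argmin(vals))]
    crit, beta, sigma_e2, A, L = _profile_eval(log_lambda, s, reml)
    lam = np.exp(log_lambda)
    if lam <= 2.0 * np.exp(_LOG_LAMBDA_BOUNDS[0]) and n_groups > 1:
        lam = 0.0
    if n_groups < 2:
        warnings.warn(
            "a single patient cannot identify the random-intercept variance; "
            "sigma_b is estimated at the zero boundary",
            NoGroupingVariance,
        )

    cov = sigma_e2 * cho_solve(L, np.eye(s.p))
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore"):
        zscores = beta / se
    p_values = 2.0 * stats.norm.sf(np.abs(zscores))
    k = s.p + (2 if bic_count_variance else 0)
    return LMMFit(
        terms=terms,
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        p_values=p_values,
        sigma_b=float(np.sqrt(lam * sigma_e2)),
        sigma_e=float(np.sqrt(sigma_e2)),
        loglik=-0.5 * crit,
        method="REML" if reml else "ML",
        n_obs=s.n,
        n_groups=n_groups,
        k_params=k,
        converged=bool(res.success),
    )


def fit_lmm(data: pd.DataFrame, spec: LMMSpec, bic_count_variance: bool = True) -> LMMFit:
    """Fit a random-intercept Gaussian LMM by ML or REML.

    Rows with missing values in any model variable are dropped.  Requires at
    least two patients for an identified sigma_b (a single patient fits at
    the zero boundary with a :class:`NoGroupingVariance` warning).
    """
    X, y, groups, terms = build_design(data, spec)
    if len(y) == 0:
        raise ValueError("no complete observations")
    s = _SuffStats.from_arrays(X, y, groups)
    return _fit_from_stats(
        s, spec.method == "REML", terms, int(groups.max()) + 1, bic_count_variance
    )


# ---------------------------------------------------------------------------
# Univariate suite, all-subsets BIC selection, Spearman matrix
# ---------------------------------------------------------------------------


def univariate_suite(
    data: pd.DataFrame,
    method: Literal["ML", "REML"] = "REML",
    candidates: Sequence[str] = CANDIDATE_TERMS,
    interactions: Sequence[str] = INTERACTION_TERMS,
) -> pd.DataFrame:
    """One mixed model per candidate variable, plus the interaction models.

    Interaction models include both main effects.  The returned table has one
    row per reported term (for interaction models, the interaction row),
    with estimate, Wald 95% CI, p-value and the number of observations used.
    """
    rows = []
    for term in candidates:
        fit = fit_lmm(data, LMMSpec((term,), method=method))
        i = fit.terms.index(term)
        rows.append(_term_row(f"{term}", term, fit, i))
    for term in interactions:
        mains = tuple(term.split(":"))
        fit = fit_lmm(data, LMMSpec((*mains, term), method=method))
        i = fit.terms.index(term)
        rows.append(_term_row(f"{mains[0]}*{mains[1]}", term, fit, i))
    return pd.DataFrame(rows)


def _term_row(model: str, term: str, fit: LMMFit, i: int) -> dict:
    return {
        "model": model,
        "term": term,
        "estimate": fit.beta[i],
        "ci_low": fit.ci_low[i],
        "ci_high": fit.ci_high[i],
        "p_value": fit.p_values[i],
        "n_obs": fit.n_obs,
        "sigma_b": fit.sigma_b,
        "sigma_e": fit.sigma_e,
    }


def dredge_bic(
    data: pd.DataFrame,
    global_terms: Sequence[str] = CANDIDATE_TERMS,
    bic_count_variance: bool = True,
) -> tuple[pd.DataFrame, LMMFit]:
    """Exhaustive all-subsets selection over the global model's fixed terms.

    Every subset (2^k models, intercept always included) is fitted by ML and
    ranked by BIC with k counting fixed effects, the intercept and (by
    default) the two variance parameters; ties break towards fewer terms.
    Returns the ranking table and the winning model refitted by REML.
    """
    global_terms = tuple(global_terms)
    spec = LMMSpec(global_terms, method="ML")
    X, y, groups, terms = build_design(data, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesign("global fixed-effect design is rank deficient")
    s_full = _SuffStats.from_arrays(X, y, groups)
    n_groups = int(groups.max()) + 1

    records = []
    for r in range(len(global_terms) + 1):
        for combo in itertools.combinations(range(len(global_terms)), r):
            idx = [0, *[c + 1 for c in combo]]
            sub_terms = ("(Intercept)", *[global_terms[c] for c in combo])
            fit = _fit_from_stats(
                s_full.subset(idx), False, sub_terms, n_groups, bic_count_variance
            )
            records.append(
                {
                    "terms": "+".join(sub_terms[1:]) or "(Intercept)",
                    "n_terms": r,
                    "loglik": fit.loglik,
                    "k": fit.k_params,
                    "BIC": fit.bic,
                }
            )
    ranking = (
        pd.DataFrame(records)
        .sort_values(["BIC", "n_terms", "terms"], kind="mergesort")
        .reset_index(drop=True)
    )
    ranking["delta_BIC"] = ranking["BIC"] - ranking["BIC"].iloc[0]
    best_terms = tuple(t for t in ranking["terms"].iloc[0].split("+") if t != "(Intercept)")
    best_fit = fit_lmm(data, LMMSpec(best_terms, method="REML"), bic_count_variance)
    return ranking, best_fit


def spearman_matrix(
    data: pd.DataFrame,
    columns: Sequence[str] = ("eccentricity", "age", "EZ", "ONL", "GCL", "RNFL"),
) -> pd.DataFrame:
    """Pairwise Spearman rank correlations across stimuli.

    Pairwise-complete observations; average-rank tie correction (ranks then
    Pearson).  A constant column yields NaN for its pairs (flagged by a
    warning).
    """
    cols = list(columns)
    if len(data.dropna(subset=cols, how="all")) < 3:
        raise ValueError("need at least 3 rows")
    out = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        out.loc[a, a] = 1.0
        for b in cols[i + 1:]:
            sub = data[[a, b]].dropna()
            if len(sub) < 3:
                continue
            if sub[a].nunique() < 2 or sub[b].nunique() < 2:
                warnings.warn(f"constant column in pair ({a}, {b}); correlation undefined")
                continue
            r = stats.spearmanr(sub[a], sub[b]).statistic
            out.loc[a, b] = out.loc[b, a] = r
    return out
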