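"""Descriptive prevalence, count/outcome correlation, and the
co-occurrence logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from ._utils import BEHAVIOR_NAMES
from .exceptions import (
    ConvergenceError,
    InputValidationError,
    SeparationError,
    UndefinedStatisticError,
)

__all__ = [
    "prevalence",
    "wilson_interval",
    "spearman_correlation",
    "fit_cooccurrence_logistic",
    "LogisticResult",
]


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise InputValidationError("n must be >= 1")
    z = scipy.stats.norm.ppf(0.5 + level / 2)
    phat = k / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def prevalence(matrix, level: float = 0.95) -> pd.DataFrame:
    """Per-behavior prevalence with Wilson CIs, ranked most-common first."""
    values = np.asarray(matrix, dtype=int)
    n, p = values.shape
    names = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else list(BEHAVIOR_NAMES[:p])
    rows = []
    for j, name in enumerate(names):
        k = int(values[:, j].sum())
        lo, hi = wilson_interval(k, n, level)
        rows.append({"behavior": name, "count": k, "proportion": k / n, "ci_low": lo, "ci_high": hi})
    out = pd.DataFrame(rows)
    out["rank"] = out["proportion"].rank(method="first", ascending=False).astype(int)
    return out.sort_values("rank").reset_index(drop=True)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rho with average-rank ties; p from the t approximation on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputValidationError("x and y must have equal length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedStatisticError("Spearman correlation undefined for constant input")
    rx = scipy.stats.rankdata(x)  # average ranks on ties
    ry = scipy.stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * scipy.stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

#: (column, reference level, non-reference output order). Economic status is
#: reported poor -> rich with "very poor" as the reference level.
CATEGORICAL_TERMS = (
    ("gender", "male", ("female",)),
    ("education_band", "0", ("1-6", "7-9", "10-12", "13+")),
    ("residence", "city", ("town", "rural")),
    ("co_residence", "household", ("alone", "institution")),
    ("economic_status", "very_poor", ("poor", "so_so", "rich", "very_rich")),
)

EDUCATION_CUTS = ((0, 0, "0"), (1, 6, "1-6"), (7, 9, "7-9"), (10, 12, "10-12"), (13, 10**9, "13+"))


def education_band(years) -> pd.Series:
    """Band education years as 0 / 1-6 / 7-9 / 10-12 / 13+."""
    y = pd.to_numeric(pd.Series(years), errors="coerce")
    out = pd.Series(pd.NA, index=y.index, dtype=object)
    for lo, hi, label in EDUCATION_CUTS:
        out[(y >= lo) & (y <= hi)] = label
    return out


@dataclass
class LogisticResult:
    """Tidy logistic-regression output on the odds-ratio scale."""

    table: pd.DataFrame  # term, level, reference, odds_ratio, ci_low, ci_high, p_value
    intercept_odds: float
    intercept_ci: tuple[float, float]
    n_used: int
    n_dropped: int
    converged: bool
    iterations: int
    log_likelihood: float
    coefficients: dict = field(default_factory=dict)  # design column -> log-odds


def _build_design(cov: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str, bool]]]:
    """Dummy-coded design matrix; returns (X, [(term, level, is_reference)])."""
    X = pd.DataFrame(index=cov.index)
    layout: list[tuple[str, str, bool]] = []
    if "gender" in cov.columns:
        layout.append(("gender", "male", True))
        X["gender[female]"] = (cov["gender"].astype(str) == "female").astype(float)
        layout.append(("gender", "female", False))
    if "age" in cov.columns:
        X["age_per_decade"] = pd.to_numeric(cov["age"], errors="coerce") / 10.0
        layout.append(("age_per_decade", "per decade", False))
    for term, ref, levels in CATEGORICAL_TERMS[1:]:
        source = term
        if term == "education_band" and term not in cov.columns:
            if "education_years" not in cov.columns:
                continue
            col = education_band(cov["education_years"])
        elif source in cov.columns:
            col = cov[source].astype(object)
        else:
            continue
        layout.append((term, ref, True))
        for lev in levels:
            X[f"{term}[{lev}]"] = (col == lev).astype(float)
            layout.append((term, lev, False))
        # propagate missingness so case-wise deletion sees it
        miss = col.isna()
        if miss.any():
            for lev in levels:
                X.loc[miss, f"{term}[{lev}]"] = np.nan
    if X.shape[1] == 0:
        raise InputValidationError("no recognized covariates present")
    return X, layout


def fit_cooccurrence_logistic(
    covariates: pd.DataFrame,
    indicator,
    level: float = 0.95,
    max_iter: int = 100,
) -> LogisticResult:
    """Binary logistic regression of the >=2-behaviors indicator on
    demographics (maximum likelihood via Newton/IRLS), reporting odds ratios
    with Wald CIs and p-values.

    Reference levels: male, 0 years education, city, living with household
    members, very poor economic status; age enters continuously per decade.
    Records missing any used covariate are dropped case-wise.
    """
    y = pd.Series(np.asarray(indicator, dtype=float), index=covariates.index)
    X, layout = _build_design(covariates)
    keep = ~(X.isna().any(axis=1) | y.isna())
    n_dropped = int((~keep).sum())
    X, y = X[keep], y[keep]
    if y.nunique() < 2:
        raise InputValidationError("indicator must contain both classes")
    # levels absent from (or universal in) the analysis sample carry no
    # information and would make the design singular; they are not estimable
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise InputValidationError("no covariate varies in the analysis sample")
    dropped_levels = {c for c in constant}

    Xc = sm.add_constant(X, prepend=True)
    model = sm.Logit(y, Xc)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False, maxiter=max_iter, method="newton")
            if not res.mle_retvals.get("converged", False):
                # Newton stalls on flat likelihoods (sparse cells); quasi-Newton
                # usually still reaches the MLE.
                res = model.fit(disp=False, maxiter=10 * max_iter, method="lbfgs")
    except np.linalg.LinAlgError as exc:  # singular Hessian: separation or collinearity
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"logistic regression did not converge in {max_iter} iterations",
            last_deviance=float(-2 * res.llf),
        )
    # a diverging coefficient signals complete separation on that term
    big = res.params.drop("const").abs() > 15
    if big.any():
        term = res.params.drop("const").abs().idxmax()
        raise SeparationError(
            f"complete separation detected on term {term!r} "
            f"(coefficient {res.params[term]:.1f})",
            term=term,
        )

    z = scipy.stats.norm.ppf(0.5 + level / 2)
    rows = []
    for term, lev, is_ref in layout:
        if is_ref:
            rows.append(
                {"term": term, "level": lev, "reference": True, "odds_ratio": 1.0,
                 "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan}
            )
            continue
        colname = "age_per_decade" if term == "age_per_decade" else f"{term}[{lev}]"
        if colname in dropped_levels:
            continue
        beta = res.params[colname]
        se = res.bse[colname]
        rows.append(
            {
                "term": term,
                "level": lev,
                "reference": False,
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - z * se)),
                "ci_high": float(np.exp(beta + z * se)),
                "p_value": float(res.pvalues[colname]),
            }
        )
    b0, se0 = res.params["const"], res.bse["const"]
    return LogisticResult(
        table=pd.DataFrame(rows),
        intercept_odds=float(np.exp(b0)),
        intercept_ci=(float(np.exp(b0 - z * se0)), float(np.exp(b0 + z * se0))),
        n_used=int(y.size),
        n_dropped=n_dropped,
        converged=True,
        iterations=int(res.mle_retvals.get("iterations", -1)),
        log_likelihood=float(res.llf),
        coefficients={k: float(v) for k, v in res.params.items()},
    )
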