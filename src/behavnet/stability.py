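"""Bootstrap stability of estimated edge weights.

Two procedures: nonparametric row-resampling bootstrap for per-edge
percentile CIs, and the case-dropping bootstrap summarized by the
CS-coefficient (largest drop fraction at which subset estimates still
correlate >= 0.7 with the full-sample estimates in >= 95% of subsets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import rng_from
from .exceptions import InputValidationError, StabilityError
from .ising import elasso_fit
from .oe import pair_label

__all__ = ["bootstrap_edge_ci", "case_dropping_stability", "CaseDroppingResult"]

DEFAULT_DROP_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


def _edge_vector(W: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(W.shape[0], k=1)
    return W[iu]


def _refit_edges(values, idx, fit_kwargs):
    sub = values[idx]
    if ((sub.mean(axis=0) == 0) | (sub.mean(axis=0) == 1)).any():
        return None
    return _edge_vector(elasso_fit(sub, **fit_kwargs).W_hat)


def bootstrap_edge_ci(
    matrix,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_failure_rate: float = 0.10,
    **fit_kwargs,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for every edge weight.

    Each replicate resamples N rows with replacement and refits eLasso at
    identical settings. Replicates where some behavior becomes constant are
    skipped and counted; more than ``max_failure_rate`` failures aborts.
    """
    values = np.asarray(matrix, dtype=int)
    N, p = values.shape
    if N < 50:
        raise InputValidationError("bootstrap requires N >= 50")
    full = elasso_fit(values, **fit_kwargs)
    point = _edge_vector(full.W_hat)
    rng = rng_from(seed)
    reps = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, N, size=N)
        edges = _refit_edges(values, idx, fit_kwargs)
        if edges is None:
            failures += 1
        else:
            reps.append(edges)
    if failures > max_failure_rate * B:
        raise StabilityError(f"{failures}/{B} bootstrap replicates failed to refit")
    reps = np.asarray(reps)
    alpha = 1 - level
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    iu = np.triu_indices(p, k=1)
    return pd.DataFrame(
        {
            "pair": [pair_label(i, j) for i, j in zip(*iu)],
            "i": iu[0],
            "j": iu[1],
            "weight": point,
            "ci_low": lo,
            "ci_high": hi,
            "replicates_used": len(reps),
            "replicates_failed": failures,
        }
    )


@dataclass
class CaseDroppingResult:
    """Per-fraction subset/full correlations and the CS-coefficient."""

    drop_fractions: tuple
    correlations: dict  # fraction -> np.ndarray of per-subset correlations (NaN = undefined)
    cs_coefficient: float
    cs_correlation_threshold: float
    cs_probability_threshold: float
    n_failed: dict

    def summary(self) -> pd.DataFrame:
        rows = []
        for f in self.drop_fractions:
            c = self.correlations[f]
            ok = c[~np.isnan(c)]
            rows.append(
                {
                    "drop_fraction": f,
                    "n_subsets": c.size,
                    "n_undefined": int(np.isnan(c).sum()),
                    "n_failed": self.n_failed[f],
                    "mean_correlation": float(ok.mean()) if ok.size else np.nan,
                    "q025": float(np.percentile(ok, 2.5)) if ok.size else np.nan,
                    "q975": float(np.percentile(ok, 97.5)) if ok.size else np.nan,
                    "prop_above_threshold": float(
                        (ok >= self.cs_correlation_threshold).sum() / c.size
                    ),
                }
            )
        return pd.DataFrame(rows)


def case_dropping_stability(
    matrix,
    drop_fractions=DEFAULT_DROP_FRACTIONS,
    B_per_fraction: int = 100,
    seed: int = 0,
    correlation_threshold: float = 0.7,
    probability_threshold: float = 0.95,
    max_failure_rate: float = 0.10,
    **fit_kwargs,
) -> CaseDroppingResult:
    """Case-dropping bootstrap of the edge-weight vector.

    For each drop fraction f, B subsets of size round(N*(1-f)) are drawn
    without replacement and refit; the Pearson correlation between the
    subset and full-sample edge vectors (all pair slots, zeros included) is
    recorded. Correlation is undefined (NaN, logged) when a subset's edge
    vector has fewer than 2 nonzero entries.
    """
    values = np.asarray(matrix, dtype=int)
    N, p = values.shape
    fmax = max(drop_fractions)
    if N * (1 - fmax) <= p:
        raise InputValidationError("largest drop fraction leaves too few records")
    full = _edge_vector(elasso_fit(values, **fit_kwargs).W_hat)
    if np.ptp(full) == 0:
        raise StabilityError("full-sample edge vector is constant; correlations undefined")
    rng = rng_from(seed)
    correlations = {}
    n_failed = {}
    for f in drop_fractions:
        size = int(round(N * (1 - f)))
        cors = np.full(B_per_fraction, np.nan)
        failures = 0
        for b in range(B_per_fraction):
            idx = rng.choice(N, size=size, replace=False)
            edges = _refit_edges(values, idx, fit_kwargs)
            if edges is None:
                failures += 1
                continue
            if (edges != 0).sum() < 2 or np.ptp(edges) == 0:
                continue  # correlation undefined on a (near-)empty refit
            cors[b] = np.corrcoef(full, edges)[0, 1]
        if failures > max_failure_rate * B_per_fraction:
            raise StabilityError(
                f"{failures}/{B_per_fraction} refits failed at drop fraction {f}"
            )
        correlations[f] = cors
        n_failed[f] = failures
    cs = 0.0
    for f in sorted(drop_fractions):
        c = correlations[f]
        prop = np.nansum(c >= correlation_threshold) / c.size
        if prop >= probability_threshold:
            cs = f
    return CaseDroppingResult(
        drop_fractions=tuple(drop_fractions),
        correlations=correlations,
        cs_coefficient=cs,
        cs_correlation_threshold=correlation_threshold,
        cs_probability_threshold=probability_threshold,
        n_failed=n_failed,
    )
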