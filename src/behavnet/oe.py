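"""Pairwise observed/expected (O/E) co-occurrence ratios.

O/E = P(A and B) / (P(A) * P(B)) for each unordered behavior pair; equals 1
under independence, > 1 when the pair clusters. Confidence intervals come
from a nonparametric percentile bootstrap of the per-record 2x2 cell vector
(default) or a normal interval on log(O/E) (delta method).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import BEHAVIOR_CODES, BEHAVIOR_NAMES, round_half_up, rng_from
from .exceptions import InputValidationError, StabilityError, UndefinedStatisticError

__all__ = [
    "PairCounts",
    "pairwise_counts",
    "oe_ratio",
    "oe_confidence_interval",
    "rank_combinations",
    "stratified_oe",
    "oe_table",
    "pair_label",
]


@dataclass(frozen=True)
class PairCounts:
    """Joint and marginal counts for one unordered behavior pair."""

    i: int
    j: int
    N: int
    n_i: int
    n_j: int
    n_ij: int

    def __post_init__(self):
        if not (0 <= self.n_ij <= min(self.n_i, self.n_j) and max(self.n_i, self.n_j) <= self.N):
            raise InputValidationError(f"inconsistent pair counts: {self}")


def pair_label(i: int, j: int, names=BEHAVIOR_NAMES, codes=BEHAVIOR_CODES) -> str:
    return f"{codes[i]}+{codes[j]}"


def pairwise_counts(matrix) -> list[PairCounts]:
    """Exact joint/marginal counts for all p(p-1)/2 column pairs."""
    values = np.asarray(matrix, dtype=int)
    if values.ndim != 2 or not np.isin(values, (0, 1)).all():
        raise InputValidationError("behavior matrix must be 2-D over {0,1}")
    N, p = values.shape
    marg = values.sum(axis=0)
    joint = values.T @ values
    return [
        PairCounts(i=i, j=j, N=N, n_i=int(marg[i]), n_j=int(marg[j]), n_ij=int(joint[i, j]))
        for i, j in combinations(range(p), 2)
    ]


def oe_ratio(pc: PairCounts) -> float:
    """(n_ij/N) / ((n_i/N)(n_j/N)); exactly 1 when n_ij*N == n_i*n_j."""
    if pc.n_i == 0 or pc.n_j == 0:
        raise UndefinedStatisticError(
            f"O/E undefined for pair ({pc.i},{pc.j}): zero marginal count"
        )
    return (pc.n_ij * pc.N) / (pc.n_i * pc.n_j)


def _log_delta_interval(pc: PairCounts, level: float) -> tuple[float, float]:
    if pc.n_ij < 1:
        raise UndefinedStatisticError("log-delta interval requires n_ij >= 1")
    z = scipy.stats.norm.ppf(0.5 + level / 2)
    var = 1 / pc.n_ij - 1 / pc.n_i - 1 / pc.n_j + 1 / pc.N
    var = max(var, 0.0)
    log_oe = np.log(oe_ratio(pc))
    half = z * np.sqrt(var)
    return float(np.exp(log_oe - half)), float(np.exp(log_oe + half))


def oe_confidence_interval(
    pc: PairCounts,
    level: float = 0.95,
    method: str = "bootstrap",
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """CI for one pair's O/E ratio.

    ``bootstrap`` resamples the 2x2 cell-count vector B times (multinomial
    over the four cells, equivalent to resampling records) and takes
    percentile bounds; replicates with a zero marginal are skipped.
    ``log-delta`` exponentiates a normal interval on log(O/E).
    """
    if method == "log-delta":
        return _log_delta_interval(pc, level)
    if method != "bootstrap":
        raise InputValidationError(f"unknown CI method {method!r}")
    if pc.N < 2:
        raise InputValidationError("bootstrap requires N >= 2")
    cells = np.array(
        [pc.n_ij, pc.n_i - pc.n_ij, pc.n_j - pc.n_ij, pc.N - pc.n_i - pc.n_j + pc.n_ij],
        dtype=float,
    )
    rng = rng_from(seed)
    draws = rng.multinomial(pc.N, cells / pc.N, size=B).astype(float)
    n_i = draws[:, 0] + draws[:, 1]
    n_j = draws[:, 0] + draws[:, 2]
    ok = (n_i > 0) & (n_j > 0)
    if not ok.any():
        raise StabilityError(
            "all bootstrap replicates degenerate (zero marginal); "
            "use method='log-delta'"
        )
    oe = draws[ok, 0] * pc.N / (n_i[ok] * n_j[ok])
    alpha = 1 - level
    lo, hi = np.percentile(oe, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def oe_table(
    matrix,
    level: float = 0.95,
    method: str = "bootstrap",
    B: int = 1000,
    seed: int = 0,
    names=None,
) -> pd.DataFrame:
    """All-pairs O/E results (unranked); pairs with a zero marginal are
    flagged ``undefined`` instead of aborting the table.
    """
    if names is None:
        p = np.asarray(matrix).shape[1]
        names = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else list(BEHAVIOR_NAMES[:p])
    rows = []
    for k, pc in enumerate(pairwise_counts(matrix)):
        row = {
            "pair": pair_label(pc.i, pc.j),
            "behavior_a": names[pc.i],
            "behavior_b": names[pc.j],
            "i": pc.i,
            "j": pc.j,
            "N": pc.N,
            "n_i": pc.n_i,
            "n_j": pc.n_j,
            "n_ij": pc.n_ij,
            "joint_percent": joint_percent(pc.n_ij, pc.N),
        }
        try:
            row["oe"] = oe_ratio(pc)
            row["undefined"] = False
        except UndefinedStatisticError:
            row.update(oe=np.nan, ci_low=np.nan, ci_high=np.nan, undefined=True)
            rows.append(row)
            continue
        try:
            row["ci_low"], row["ci_high"] = oe_confidence_interval(
                pc, level=level, method=method, B=B, seed=seed + k
            )
        except (UndefinedStatisticError, InputValidationError, StabilityError):
            # point estimate stands; interval is not computable (e.g. N=1)
            row["ci_low"] = row["ci_high"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def joint_percent(n_ij: int, N: int) -> float:
    """100 * n_ij / N rounded half-up to two decimals (printed-table style)."""
    return round_half_up(100.0 * n_ij / N, 2)


def rank_combinations(results: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """Rank defined pairs by descending O/E; ties break toward larger n_ij,
    then lexicographic pair label. Returns the top ``top_k`` (clamped).
    """
    defined = results[~results["undefined"]].copy()
    defined = defined.sort_values(
        by=["oe", "n_ij", "pair"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    defined["rank"] = np.arange(1, len(defined) + 1)
    return defined.head(max(0, min(top_k, len(defined))))


def stratified_oe(
    matrix,
    strata,
    level: float = 0.95,
    method: str = "bootstrap",
    B: int = 1000,
    seed: int = 0,
    top_k: int = 10,
) -> dict[str, pd.DataFrame]:
    """Full ranked O/E pipeline per stratum (stratum-specific N)."""
    values = np.asarray(matrix, dtype=int)
    labels = np.asarray(strata)
    if labels.size != values.shape[0]:
        raise InputValidationError("strata must label every record")
    out = {}
    for lab in pd.unique(labels):
        sub = values[labels == lab]
        table = oe_table(
            sub,
            level=level,
            method=method,
            B=B,
            seed=seed,
            names=list(matrix.columns) if isinstance(matrix, pd.DataFrame) else None,
        )
        out[str(lab)] = rank_combinations(table, top_k=top_k)
    return out
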