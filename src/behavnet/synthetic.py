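"""Synthetic survey-data generator.

Samples exactly from a parameterized binary pairwise Markov random field
(Ising model) over seven health-risk behaviors, plants demographic effects
on the "two or more behaviors" indicator, and emits raw survey-style
responses that :mod:`behavnet.coding` can re-code into the same binary
matrix. Everything is a pure function of (config, seed).

The joint distribution is enumerated exactly (2^p states), which keeps the
generator free of MCMC burn-in questions and provides closed-form oracles
(true marginals, true pairwise O/E ratios) for estimator tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._utils import BEHAVIOR_NAMES, rng_from
from .exceptions import (
    CapacityError,
    GenerationError,
    InvalidParametersError,
    UndefinedStatisticError,
)

__all__ = [
    "IsingParameters",
    "JointPmf",
    "SyntheticConfig",
    "enumerate_joint_pmf",
    "sample_behaviors",
    "true_pairwise_oe",
    "generate_survey_table",
    "default_ising_parameters",
    "write_survey_csv",
]

MAX_ENUMERABLE_P = 20


@dataclass(frozen=True)
class IsingParameters:
    """Node thresholds tau and symmetric zero-diagonal coupling matrix W."""

    tau: np.ndarray
    W: np.ndarray

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "W", W)
        if tau.ndim != 1 or tau.size < 2:
            raise InvalidParametersError("tau must be a vector of length >= 2")
        if W.shape != (tau.size, tau.size):
            raise InvalidParametersError(
                f"W must be {tau.size}x{tau.size}, got {W.shape}"
            )
        if not np.allclose(W, W.T, atol=0, rtol=0):
            raise InvalidParametersError("W must be exactly symmetric")
        if np.any(np.diag(W) != 0):
            raise InvalidParametersError("W must have a zero diagonal")

    @property
    def p(self) -> int:
        return self.tau.size


@dataclass(frozen=True)
class JointPmf:
    """Exact joint pmf over all 2^p binary states.

    States are in binary-counting order with behavior 1 in the least
    significant position: state index s has x_k = (s >> k) & 1.
    """

    states: np.ndarray  # (2^p, p) in {0,1}
    probs: np.ndarray  # (2^p,), sums to 1

    @property
    def p(self) -> int:
        return self.states.shape[1]

    def marginal(self, i: int) -> float:
        """P(x_i = 1)."""
        return float(self.probs[self.states[:, i] == 1].sum())


def _all_states(p: int) -> np.ndarray:
    idx = np.arange(2**p, dtype=np.int64)
    return ((idx[:, None] >> np.arange(p)) & 1).astype(np.int8)


def enumerate_joint_pmf(params: IsingParameters) -> JointPmf:
    """Enumerate the exact Ising joint distribution.

    P(x) is proportional to exp(sum_i tau_i x_i + sum_{i<j} w_ij x_i x_j),
    normalized by the full partition sum over all 2^p states.
    """
    p = params.p
    if p > MAX_ENUMERABLE_P:
        raise CapacityError(f"cannot enumerate 2^{p} states (limit p <= {MAX_ENUMERABLE_P})")
    states = _all_states(p)
    x = states.astype(float)
    # energy per state: tau'x + x'Wx/2 (W symmetric, zero diagonal)
    energy = x @ params.tau + 0.5 * np.einsum("si,ij,sj->s", x, params.W, x)
    energy -= energy.max()  # numerical stability; cancels in normalization
    weights = np.exp(energy)
    probs = weights / weights.sum()
    return JointPmf(states=states, probs=probs)


def sample_behaviors(pmf: JointPmf, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` iid rows from an enumerated joint pmf.

    Returns an (n, p) int8 matrix; identical (pmf, n, seed) gives
    bit-identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng_from(seed)
    idx = rng.choice(pmf.probs.size, size=n, p=pmf.probs)
    return pmf.states[idx].copy()


def true_pairwise_oe(pmf: JointPmf, i: int, j: int) -> float:
    """Exact model-level O/E ratio P(x_i=1, x_j=1) / (P(x_i=1) P(x_j=1)).

    Serves as the ground-truth oracle for the sample estimator.
    """
    if i == j:
        raise ValueError("i and j must be distinct nodes")
    pi = pmf.marginal(i)
    pj = pmf.marginal(j)
    if pi == 0 or pj == 0:
        raise UndefinedStatisticError(
            f"O/E undefined: node {i if pi == 0 else j} has zero marginal"
        )
    both = (pmf.states[:, i] == 1) & (pmf.states[:, j] == 1)
    pij = float(pmf.probs[both].sum())
    return pij / (pi * pj)


# ---------------------------------------------------------------------------
# survey-table generation
# ---------------------------------------------------------------------------

#: Age bands used for covariate sampling: (label, low, high inclusive).
AGE_BANDS = (("65-74", 65, 74), ("75-84", 75, 84), ("85-94", 85, 94), ("95+", 95, 105))
EDUCATION_BANDS = (("0", 0, 0), ("1-6", 1, 6), ("7-9", 7, 9), ("10-12", 10, 12), ("13+", 13, 18))


def _normalized(labels, weights) -> dict:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return dict(zip(labels, w.tolist()))


def _default_covariate_distributions() -> dict:
    # Marginals echo a large national survey of older adults; bands with a
    # small "missing" share are renormalized over observed categories.
    return {
        "gender": _normalized(["male", "female"], [0.4615, 0.5385]),
        "age_band": _normalized([b[0] for b in AGE_BANDS], [0.2370, 0.2905, 0.2504, 0.2221]),
        "residence": _normalized(["city", "town", "rural"], [0.2236, 0.3339, 0.4425]),
        "education_band": _normalized(
            [b[0] for b in EDUCATION_BANDS], [0.4055, 0.2854, 0.0873, 0.0512, 0.0309]
        ),
        "co_residence": _normalized(["household", "alone", "institution"], [0.7963, 0.1617, 0.0301]),
        "economic_status": _normalized(
            ["very_rich", "rich", "so_so", "poor", "very_poor"],
            [0.0260, 0.1706, 0.6948, 0.0877, 0.0125],
        ),
    }


def _default_cooccurrence_log_odds() -> dict:
    """Planted effects on the >=2-behaviors indicator (log-odds scale)."""
    ln = math.log
    return {
        "intercept": ln(1.78),
        "age_per_decade": ln(1.15),
        "gender": {"female": ln(1.86)},
        "education_band": {"1-6": ln(0.79), "7-9": ln(0.67), "10-12": ln(0.51), "13+": ln(0.46)},
        "residence": {"town": ln(2.30), "rural": ln(2.42)},
        "co_residence": {"alone": ln(1.18), "institution": ln(0.96)},
        "economic_status": {
            "poor": ln(0.74),
            "so_so": ln(0.35),
            "rich": ln(0.21),
            "very_rich": ln(0.22),
        },
    }


def default_ising_parameters() -> IsingParameters:
    """Default 7-node generator: two planted positive blocks.

    Block A (addictive): salty_diet, smoking, drinking.
    Block B (activity/eating): fruit, vegetable, exercise, sleep.
    Thresholds are calibrated so the seven marginal prevalences span roughly
    0.10 (insufficient vegetable, rarest) to 0.75 (irregular exercise, most
    common).
    """
    p = 7
    W = np.zeros((p, p))
    block_a = [2, 3, 4]
    block_b = [0, 1, 5, 6]
    for bi, block, w in ((0, block_a, 0.9), (1, block_b, 0.5)):
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                W[block[a], block[b]] = W[block[b], block[a]] = w
    # calibrated against target marginals (0.35, 0.10, 0.15, 0.17, 0.15, 0.75, 0.25)
    tau = np.array([-1.1879, -2.9458, -2.1141, -1.9347, -2.1141, 0.7864, -1.7348])
    return IsingParameters(tau=tau, W=W)


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic dataset."""

    n_records: int = 1000
    seed: int = 0
    ising: IsingParameters = field(default_factory=default_ising_parameters)
    covariate_distributions: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_covariate_distributions
    )
    cooccurrence_log_odds: Mapping = field(default_factory=_default_cooccurrence_log_odds)
    #: scale of the negative behavior-count loading on the latent outcome
    #: score; default calibrated so Spearman(count, outcome) is about -0.17.
    outcome_link_strength: float = 0.19
    #: MCAR missingness applied to education/co-residence/economic status only.
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.n_records < 1:
            raise InvalidParametersError("n_records must be >= 1")
        for name, dist in self.covariate_distributions.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidParametersError(
                    f"covariate distribution {name!r} sums to {total}, not 1"
                )
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidParametersError("missing_rate must be in [0, 1)")


def _sample_categorical(rng, dist: Mapping[str, float], n: int) -> np.ndarray:
    labels = list(dist.keys())
    probs = np.array([dist[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=n, p=probs)


def _planted_log_odds(cfg: SyntheticConfig, cov: pd.DataFrame) -> np.ndarray:
    lo = cfg.cooccurrence_log_odds
    eta = np.full(len(cov), float(lo.get("intercept", 0.0)))
    eta += float(lo.get("age_per_decade", 0.0)) * cov["age"].to_numpy() / 10.0
    for field_name in ("gender", "education_band", "residence", "co_residence", "economic_status"):
        effects = lo.get(field_name, {})
        if not effects:
            continue
        col = cov[field_name].to_numpy()
        for level, beta in effects.items():
            eta[col == level] += float(beta)
    return eta


def _count_conditional_pmfs(pmf: JointPmf):
    """Split the enumerated pmf into count>=2 and count<=1 conditionals."""
    counts = pmf.states.sum(axis=1)
    out = {}
    for key, mask in (("ge2", counts >= 2), ("le1", counts <= 1)):
        mass = pmf.probs[mask].sum()
        if mass <= 0:
            raise GenerationError(
                f"conditional state set empty: no probability mass on stratum {key!r}"
            )
        out[key] = (np.flatnonzero(mask), pmf.probs[mask] / mass)
    return out


_RATING_LETTERS = {5: "A", 4: "B", 3: "C", 2: "D", 1: "E"}
_OUTCOME_CUTS = np.array([-1.5, -0.5, 0.5, 1.5])


def _ordinal_outcome(rng, count: np.ndarray, strength: float) -> np.ndarray:
    """Scores 1-5 from a latent normal with negative loading on count."""
    c = count.astype(float)
    sd = c.std()
    z = (c - c.mean()) / sd if sd > 0 else np.zeros_like(c)
    latent = -strength * z + rng.standard_normal(c.size)
    latent = (latent - latent.mean()) / latent.std()
    return 1 + (latent[:, None] > _OUTCOME_CUTS[None, :]).sum(axis=1)


def generate_survey_table(config: SyntheticConfig, return_truth: bool = False):
    """Generate a raw survey-style table (and optionally the hidden truth).

    Steps: (a) covariates from configured categoricals; (b) a >=2-behaviors
    indicator from the planted logistic model; (c) the 7-vector of behaviors
    from the Ising pmf conditioned on behavior count matching the indicator;
    (d) two ordinal outcomes from a latent score with negative loading on the
    behavior count; (e) raw response fields from which the binary matrix can
    be re-derived exactly.
    """
    rng = rng_from(config.seed)
    n = config.n_records
    pmf = enumerate_joint_pmf(config.ising)

    # (a) covariates
    cov = pd.DataFrame(index=pd.RangeIndex(n))
    dists = config.covariate_distributions
    cov["gender"] = _sample_categorical(rng, dists["gender"], n)
    cov["age_band"] = _sample_categorical(rng, dists["age_band"], n)
    band_range = {b[0]: (b[1], b[2]) for b in AGE_BANDS}
    lo = np.array([band_range[b][0] for b in cov["age_band"]])
    hi = np.array([band_range[b][1] for b in cov["age_band"]])
    cov["age"] = rng.integers(lo, hi + 1)
    cov["residence"] = _sample_categorical(rng, dists["residence"], n)
    cov["education_band"] = _sample_categorical(rng, dists["education_band"], n)
    edu_range = {b[0]: (b[1], b[2]) for b in EDUCATION_BANDS}
    elo = np.array([edu_range[b][0] for b in cov["education_band"]])
    ehi = np.array([edu_range[b][1] for b in cov["education_band"]])
    cov["education_years"] = rng.integers(elo, ehi + 1)
    cov["co_residence"] = _sample_categorical(rng, dists["co_residence"], n)
    cov["economic_status"] = _sample_categorical(rng, dists["economic_status"], n)

    # (b) planted co-occurrence indicator
    eta = _planted_log_odds(config, cov)
    prob_ge2 = 1.0 / (1.0 + np.exp(-eta))
    indicator = rng.random(n) < prob_ge2

    # (c) behaviors from the count-conditioned Ising pmf
    conditionals = _count_conditional_pmfs(pmf)
    behaviors = np.empty((n, pmf.p), dtype=np.int8)
    for key, mask in (("ge2", indicator), ("le1", ~indicator)):
        m = int(mask.sum())
        if m == 0:
            continue
        state_idx, cond_probs = conditionals[key]
        draws = rng.choice(state_idx.size, size=m, p=cond_probs)
        behaviors[mask] = pmf.states[state_idx[draws]]
    count = behaviors.sum(axis=1)

    # (d) ordinal outcomes
    qol_score = _ordinal_outcome(rng, count, config.outcome_link_strength)
    health_score = _ordinal_outcome(rng, count, config.outcome_link_strength)

    # (e) raw responses that re-code to exactly `behaviors`
    freq_risky = np.array(["C", "D"])
    freq_safe = np.array(["A", "B"])
    flavors_safe = np.array(["bland", "neutral", "sweet", "spicy"])

    def freq_field(col):
        return np.where(
            behaviors[:, col] == 1,
            freq_risky[rng.integers(0, 2, n)],
            freq_safe[rng.integers(0, 2, n)],
        )

    table = pd.DataFrame(
        {
            "record_id": np.arange(n),
            "gender": cov["gender"],
            "age": cov["age"],
            "residence": cov["residence"],
            "education_years": cov["education_years"],
            "co_residence": cov["co_residence"],
            "economic_status": cov["economic_status"],
            "sleep_hours": np.where(
                behaviors[:, 6] == 1, rng.integers(3, 6, n), rng.integers(6, 11, n)
            ),
            "fruit_freq": freq_field(0),
            "veg_freq": freq_field(1),
            "flavor": np.where(
                behaviors[:, 2] == 1, "salty", flavors_safe[rng.integers(0, 4, n)]
            ),
            "smoking_now": np.where(behaviors[:, 3] == 1, "yes", "no"),
            "drinking_now": np.where(behaviors[:, 4] == 1, "yes", "no"),
            "regular_exercise": np.where(behaviors[:, 5] == 1, "no", "yes"),
            "qol_rating": [_RATING_LETTERS[s] for s in qol_score],
            "health_rating": [_RATING_LETTERS[s] for s in health_score],
        }
    )

    if config.missing_rate > 0:
        for colname in ("education_years", "co_residence", "economic_status"):
            mask = rng.random(n) < config.missing_rate
            table.loc[mask, colname] = np.nan

    if return_truth:
        truth = {
            "behaviors": behaviors,
            "behavior_names": list(BEHAVIOR_NAMES),
            "count": count,
            "indicator_ge2": indicator,
            "prob_ge2": prob_ge2,
            "qol_score": qol_score,
            "health_score": health_score,
        }
        return table, truth
    return table


def write_survey_csv(table: pd.DataFrame, path, config: SyntheticConfig | None = None) -> None:
    """Write the table as UTF-8 CSV plus a JSON provenance sidecar."""
    table.to_csv(path, index=False, encoding="utf-8")
    if config is not None:
        sidecar = {
            "n_records": config.n_records,
            "seed": config.seed,
            "ising": {"tau": config.ising.tau.tolist(), "W": config.ising.W.tolist()},
            "covariate_distributions": {
                k: dict(v) for k, v in config.covariate_distributions.items()
            },
            "cooccurrence_log_odds": json.loads(json.dumps(config.cooccurrence_log_odds)),
            "outcome_link_strength": config.outcome_link_strength,
            "missing_rate": config.missing_rate,
            "behavior_columns": list(BEHAVIOR_NAMES),
        }
        with open(f"{path}.params.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2)
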