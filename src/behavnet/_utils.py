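"""Shared numeric and provenance helpers."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

#: Canonical behavior column order used throughout the package. Outputs
#: always carry these names so every table is self-describing.
BEHAVIOR_NAMES = (
    "insufficient_fruit",
    "insufficient_vegetable",
    "salty_diet",
    "smoking",
    "drinking",
    "irregular_exercise",
    "inadequate_sleep",
)

#: Short circled-digit codes for compact pair labels in ranked tables.
BEHAVIOR_CODES = ("B1", "B2", "B3", "B4", "B5", "B6", "B7")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (half-up), not banker's rounding.

    Printed percentages in the reference tables use half-up rounding, which
    differs from Python's built-in ``round`` on exact .5 ties.
    """
    quant = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-specific 32-bit seed from a master seed.

    Stable across processes and Python versions (sha256, not ``hash``), so a
    stage can be re-run in isolation and reproduce the pipeline's draw.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def sigfig(value: float, digits: int = 12) -> float:
    """Round a float to ``digits`` significant digits for stable serialization."""
    if value == 0 or not np.isfinite(value):
        return float(value)
    return float(f"{value:.{digits}g}")


def json_roundable(obj):
    """Recursively convert numpy scalars/arrays and round floats to 12 s.f."""
    if isinstance(obj, dict):
        return {str(k): json_roundable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [json_roundable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [json_roundable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        return sigfig(float(obj))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj
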