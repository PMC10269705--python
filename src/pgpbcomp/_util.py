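"""Small shared helpers."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal

HABITATS = ("LA", "SA", "OA")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed percentages).

    Python's builtin ``round`` is banker's rounding; reported percentage
    shares use half-up so 0.275 -> 0.28.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: float, total: float, ndigits: int = 2) -> float:
    """Percentage share rounded half-up; total must be positive."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


def derive_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from a root seed.

    Hash-based so each pipeline stage can be rerun alone with the same
    stream it saw inside a full run.
    """
    digest = hashlib.sha256(f"{int(root_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
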