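"""Small shared helpers (rounding, validation)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round to ``decimals`` places with ties going away from zero.

    Printed percentages and frequencies in reports use this convention
    (banker's rounding would turn e.g. 0.25 into 0.2 instead of 0.3).
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def require(condition: bool, message: str) -> None:
    """Raise ``ValueError`` with ``message`` unless ``condition`` holds."""
    if not condition:
        raise ValueError(message)
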