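"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
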