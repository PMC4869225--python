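from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching how the share tables print.

    Python's builtin ``round`` is banker's rounding; percentage tables are
    conventionally printed half-up, so 0.125 -> 0.13 at 2 dp.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
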