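"""Presentation rounding.

All computation in this package runs at full floating precision; rounding
happens only when values are compared against, or formatted like, printed
tables. Printed half-way cases in the source tables (e.g. a mean of 5.045
printed as 5.05) show the tables were produced with round-half-up, not the
round-half-even convention of Python's builtin ``round``.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, halves away from zero.

    The float is first snapped to 10 decimals so that binary representation
    artifacts (5.0449999999999995 for an exact decimal 5.045) do not flip a
    half-way case.
    """
    q = Decimal(1).scaleb(-ndigits)
    snapped = Decimal(f"{x:.10f}")
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))
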