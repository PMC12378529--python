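"""Unit handling: A1c NGSP(%) <-> IFCC(mmol/mol) and half-up rounding.

Every printed value in the reporting tables is rounded *half-up* at a fixed
display precision, and several downstream quantities are computed from the
rounded (not the raw) values, so the rounding helpers here are load-bearing,
not cosmetic.  Python's builtin ``round`` is half-even and floats carry binary
representation error (``round(142.5)`` -> 142, ``round(1.335, 2)`` -> 1.33),
so rounding goes through :mod:`decimal` on the shortest repr of the float.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

from .errors import DomainError

# NGSP/IFCC master equation coefficients (the standard harmonisation line).
_IFCC_SLOPE = 10.93
_IFCC_OFFSET = -23.50

#: Smallest NGSP % with a positive IFCC image (10.93 * x - 23.50 > 0).
A1C_PERCENT_MIN = 2.15


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero upward.

    ``round_half_up(142.5) == 143.0`` and ``round_half_up(1.335, 2) == 1.34``,
    matching how the reporting tables are printed.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def round_half_up_int(x: float) -> int:
    """Half-up rounding to the nearest integer."""
    return int(round_half_up(x, 0))


def a1c_percent_to_ifcc(a1c_percent: float) -> int:
    """Convert A1c from NGSP percent to IFCC mmol/mol (nearest integer).

    Uses the master equation ``IFCC = 10.93 * NGSP - 23.50``; the result is
    reported at the integer precision laboratories print.

    Parameters
    ----------
    a1c_percent : float
        A1c on the NGSP scale, in percent.  Must exceed 2.15% so the IFCC
        image is positive.

    Returns
    -------
    int
        A1c in mmol/mol.

    Examples
    --------
    >>> a1c_percent_to_ifcc(5.0)
    31
    >>> a1c_percent_to_ifcc(5.7)
    39
    """
    if not a1c_percent > A1C_PERCENT_MIN:
        raise DomainError(
            f"A1c {a1c_percent}% is at or below {A1C_PERCENT_MIN}%, "
            "outside the domain of the NGSP->IFCC conversion"
        )
    return round_half_up_int(_IFCC_SLOPE * a1c_percent + _IFCC_OFFSET)


def a1c_ifcc_to_percent(a1c_mmol_mol: float, ndigits: int = 1) -> float:
    """Convert A1c from IFCC mmol/mol back to NGSP percent (1 dp by default).

    Round-trips with :func:`a1c_percent_to_ifcc` within one quantisation unit
    (+/-0.05% at 1 dp).
    """
    if a1c_mmol_mol <= 0:
        raise DomainError(f"A1c {a1c_mmol_mol} mmol/mol must be positive")
    return round_half_up((a1c_mmol_mol - _IFCC_OFFSET) / _IFCC_SLOPE, ndigits)
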