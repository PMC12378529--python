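"""Core glycation metrics for a single biomarker panel.

The model expresses an individual's glycation as a ratio to the optimum for
two measurable glycated proteins (A1c at half-life 28.7 d, fructosamine at
16.5 d) and extrapolates that ratio to the unmeasurable targets (cTnI at 1 d,
LDL at 3 d) along the straight line through the two anchors in
(half-life, ratio) space:

    m = (rF - rA) / (16.5 - 28.7),   b = rA - m * 28.7,   rate(h) = m*h + b

giving the troponin glycation rate TGR = rate(1) and LDL glycation rate
LGR = rate(3).  Multiplying by the circulating concentration gives the
glycation indices TGI = TGR x cTnI and LGI = LGR x LDL, read as the total
glycated fraction of the biomarker pool.

Rounding protocol (load-bearing for reproducing the reporting tables):
concentration ratios to 2 dp *before* the slope-intercept step; rates to
2 dp; TGI to 1 dp; LGI to the nearest integer; all ties half-up.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Union

from .constants import DEFAULT_CONSTANTS, ReferenceConstants
from .errors import DegenerateGeometryError, DomainError, ValidationError
from .units import (
    a1c_ifcc_to_percent,
    a1c_percent_to_ifcc,
    round_half_up,
    round_half_up_int,
)


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"

    @classmethod
    def coerce(cls, value: Union[str, "Sex"]) -> "Sex":
        if isinstance(value, Sex):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValidationError(
                f"sex must be 'female' or 'male', got {value!r}"
            ) from None


class A1cUnits(str, enum.Enum):
    PERCENT = "percent"
    MMOL_MOL = "mmol/mol"

    @classmethod
    def coerce(cls, value: Union[str, "A1cUnits"]) -> "A1cUnits":
        if isinstance(value, A1cUnits):
            return value
        text = str(value).strip().lower()
        aliases = {
            "percent": cls.PERCENT,
            "%": cls.PERCENT,
            "ngsp": cls.PERCENT,
            "mmol/mol": cls.MMOL_MOL,
            "mmol_mol": cls.MMOL_MOL,
            "ifcc": cls.MMOL_MOL,
        }
        try:
            return aliases[text]
        except KeyError:
            raise ValidationError(
                f"a1c units must be 'percent' or 'mmol/mol', got {value!r}"
            ) from None


@dataclass(frozen=True)
class BiomarkerPanel:
    """One dated laboratory draw: A1c, fructosamine, cTnI and direct LDL.

    The A1c unit system is tagged explicitly (``percent`` NGSP or
    ``mmol/mol`` IFCC) and never inferred from magnitude.
    """

    draw_date: dt.date
    sex: Sex
    a1c: float
    a1c_units: Union[A1cUnits, str]
    fructosamine: float  # µmol/L
    ctni: float          # ng/L
    ldl: float           # mg/dL

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex.coerce(self.sex))
        object.__setattr__(self, "a1c_units", A1cUnits.coerce(self.a1c_units))
        if isinstance(self.draw_date, dt.datetime):
            object.__setattr__(self, "draw_date", self.draw_date.date())
        elif isinstance(self.draw_date, str):
            object.__setattr__(
                self, "draw_date", dt.date.fromisoformat(self.draw_date)
            )
        for name in ("a1c", "fructosamine", "ctni", "ldl"):
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(
                    f"{name} must be strictly positive, got {value!r}"
                )

    @property
    def year(self) -> int:
        return self.draw_date.year

    @property
    def a1c_ifcc(self) -> float:
        """A1c on the IFCC scale (mmol/mol); converts from percent if needed."""
        if self.a1c_units is A1cUnits.PERCENT:
            return float(a1c_percent_to_ifcc(self.a1c))
        return float(self.a1c)

    @property
    def a1c_percent(self) -> float:
        """A1c on the NGSP scale (%), 1 dp; converts from mmol/mol if needed."""
        if self.a1c_units is A1cUnits.PERCENT:
            return float(self.a1c)
        return a1c_ifcc_to_percent(self.a1c)


@dataclass(frozen=True)
class GlycationMetrics:
    """Derived glycation quantities for one panel.

    ``slope``/``intercept`` are kept unrounded; the display roundings applied
    to the derived fields are part of the metric definitions (see module
    docstring).
    """

    ratio_a1c: float           # rA = Y1, anchor at X1 = A1c half-life
    ratio_fructosamine: float  # rF = Y2, anchor at X2 = fructosamine half-life
    slope: float               # m, per day
    intercept: float           # b
    tgr: float                 # rate(ctni half-life), 2 dp
    lgr: float                 # rate(ldl half-life), 2 dp
    tgi: float                 # TGR x cTnI, 1 dp (ng/L-scaled)
    lgi: int                   # LGR x LDL, integer (mg/dL-scaled)

    @property
    def glycation_gap(self) -> float:
        """rA - rF: the A1c-implied minus fructosamine-implied glycation."""
        return self.ratio_a1c - self.ratio_fructosamine


def concentration_ratio(observed: float, optimal: float) -> float:
    """Ratio of an observed analyte value to its optimal reference, 2 dp.

    A1c ratios are computed on the IFCC (mmol/mol) scale; the 2-dp rounding is
    applied *here*, before any extrapolation, because downstream rates are
    defined on the rounded ratios.

    Examples
    --------
    >>> concentration_ratio(39, 31)
    1.26
    >>> concentration_ratio(240, 200)
    1.2
    """
    if not optimal > 0:
        raise DomainError(f"optimal reference must be positive, got {optimal!r}")
    if not observed > 0:
        raise DomainError(f"observed value must be positive, got {observed!r}")
    return round_half_up(observed / optimal, 2)


def slope_intercept(
    ratio_a1c: float,
    ratio_fructosamine: float,
    constants: ReferenceConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Unrounded (m, b) of the line through the two ratio anchors."""
    x1 = constants.halflife_a1c
    x2 = constants.halflife_fructosamine
    if x1 == x2:
        raise DegenerateGeometryError(
            f"anchor half-lives coincide at {x1} d; the two-point line is undefined"
        )
    m = (ratio_fructosamine - ratio_a1c) / (x2 - x1)
    b = ratio_a1c - m * x1
    return m, b


def rate_at_halflife(
    ratio_a1c: float,
    ratio_fructosamine: float,
    target_halflife: float,
    constants: ReferenceConstants = DEFAULT_CONSTANTS,
) -> float:
    """Glycation rate extrapolated to ``target_halflife`` days, 2 dp.

    Equivalent (before rounding) to the closed form
    ``rF + (rA - rF) * (h - x2) / (x1 - x2)``.

    Examples
    --------
    >>> rate_at_halflife(1.26, 1.20, 1)
    1.12
    >>> rate_at_halflife(1.26, 1.20, 3)
    1.13
    """
    if not target_halflife > 0:
        raise DomainError(
            f"target half-life must be positive, got {target_halflife!r}"
        )
    m, b = slope_intercept(ratio_a1c, ratio_fructosamine, constants)
    return round_half_up(m * target_halflife + b, 2)


def compute_metrics(
    panel: BiomarkerPanel,
    constants: ReferenceConstants = DEFAULT_CONSTANTS,
) -> GlycationMetrics:
    """All glycation metrics for one panel under the rounding protocol."""
    ra = concentration_ratio(panel.a1c_ifcc, constants.optimal_a1c)
    rf = concentration_ratio(panel.fructosamine, constants.optimal_fructosamine)
    m, b = slope_intercept(ra, rf, constants)
    tgr = rate_at_halflife(ra, rf, constants.halflife_ctni, constants)
    lgr = rate_at_halflife(ra, rf, constants.halflife_ldl, constants)
    return GlycationMetrics(
        ratio_a1c=ra,
        ratio_fructosamine=rf,
        slope=m,
        intercept=b,
        tgr=tgr,
        lgr=lgr,
        tgi=round_half_up(tgr * panel.ctni, 1),
        lgi=round_half_up_int(lgr * panel.ldl),
    )
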