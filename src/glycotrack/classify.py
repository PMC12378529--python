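"""Quartile banding and exclusionary screening.

The quartile table places each biomarker and metric into one of four fixed
bands spanning the modelled range (cTnI from the 1.6 ng/L detection limit to
the sex-specific exclusion ceiling, rates from the optimum 1.0 to the 1.5
cap, indices from rate x concentration at the respective endpoints).  Bands
are closed on both printed endpoints; the printed bounds sit at measurement
precision, so any value falling in the gap between consecutive bands (e.g.
a rate of 1.155 between 1.15 and 1.16) is assigned to the lower band, which
makes classification total over the modelled range.

Screening flags analytes strictly above their exclusion ceilings: such
values point at overt disease (diabetes, severe hyperlipidemia, cardiac
injury) where the proxy model no longer applies and diagnostic work-up is
indicated instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

from .constants import (
    DEFAULT_CONSTANTS,
    DEFAULT_LIMITS,
    RATE_MAX_DEFAULT,
    ExclusionLimits,
    ReferenceConstants,
)
from .errors import ConfigError
from .metrics import BiomarkerPanel, Sex
from .units import round_half_up

#: Marker returned for values below the table's overall domain.
BELOW_RANGE = "below-range"
#: Marker returned for values above the table's overall domain.
ABOVE_RANGE = "above-range"

METRIC_NAMES = ("ctni", "tgr", "tgi", "ldl", "lgr", "lgi")
_SEX_SPECIFIC = ("ctni", "tgi")


@dataclass(frozen=True)
class Band:
    """One quartile band, closed on both endpoints; ``upper=None`` is open."""

    lower: float
    upper: Optional[float]

    def describe(self) -> str:
        if self.upper is None:
            return f">{self.lower:g}"
        return f"{self.lower:g}–{self.upper:g}"


class QuartileTable:
    """Fixed quartile bands per metric, with sex-specific cTnI/TGI edges.

    ``bands`` maps ``(metric, sex)`` to an ordered list of four
    :class:`Band`; metrics without sex dependence store identical lists for
    both sexes.  ``default()`` derives the published table from the model
    constants: the quartile-3 upper edge for cTnI is the sex-specific
    exclusion ceiling and for TGI the ceiling times the 1.5 rate cap, so
    adjusting ``ctni_max_male`` (legitimate within 5-7 ng/L) moves only the
    male cTnI/TGI band-3/4 edges.
    """

    def __init__(self, bands: dict[tuple[str, Sex], list[Band]]):
        for metric in METRIC_NAMES:
            for sex in Sex:
                key = (metric, sex)
                if key not in bands:
                    raise ConfigError(f"quartile table missing bands for {key}")
                if len(bands[key]) != 4:
                    raise ConfigError(f"{key} must have exactly 4 bands")
                seq = bands[key]
                # open-band quartile 4 is printed ">x" with x = band 3's upper
                # edge, so equality of the shared edge is allowed there
                for lo, hi in zip(seq, seq[1:]):
                    if lo.upper is None or lo.upper > hi.lower:
                        raise ConfigError(
                            f"bands for {key} must be ordered and non-overlapping"
                        )
        self._bands = bands

    @classmethod
    def default(
        cls,
        limits: ExclusionLimits = DEFAULT_LIMITS,
        constants: ReferenceConstants = DEFAULT_CONSTANTS,
        rate_max: float = RATE_MAX_DEFAULT,
    ) -> "QuartileTable":
        bands: dict[tuple[str, Sex], list[Band]] = {}
        ctni_max = {Sex.FEMALE: limits.ctni_max_female, Sex.MALE: limits.ctni_max_male}
        for sex in Sex:
            tgi_max = round_half_up(rate_max * ctni_max[sex], 2)
            bands[("ctni", sex)] = [
                Band(constants.ctni_lod, 2.4),
                Band(2.5, 3.3),
                Band(3.4, ctni_max[sex]),
                Band(ctni_max[sex], None),
            ]
            bands[("tgi", sex)] = [
                Band(1.6, 2.8),
                Band(2.9, 4.3),
                Band(4.4, tgi_max),
                Band(tgi_max, None),
            ]
            rate_bands = [
                Band(1.0, 1.15),
                Band(1.16, 1.31),
                Band(1.32, rate_max),
                Band(rate_max, None),
            ]
            bands[("tgr", sex)] = rate_bands
            bands[("lgr", sex)] = list(rate_bands)
            bands[("ldl", sex)] = [
                Band(constants.ldl_floor, 90),
                Band(91, 121),
                Band(122, 152),
                Band(153, limits.ldl_max),
            ]
            bands[("lgi", sex)] = [
                Band(60, 104),
                Band(105, 160),
                Band(161, 228),
                Band(229, 270),
            ]
        return cls(bands)

    def bands_for(self, metric: str, sex: Union[Sex, str, None] = None) -> list[Band]:
        metric = str(metric).strip().lower()
        if metric not in METRIC_NAMES:
            raise ConfigError(
                f"unknown metric {metric!r}; expected one of {METRIC_NAMES}"
            )
        if metric in _SEX_SPECIFIC and sex is None:
            raise ConfigError(f"metric {metric!r} requires sex for classification")
        sex = Sex.coerce(sex) if sex is not None else Sex.FEMALE
        return self._bands[(metric, sex)]

    def classify(
        self, metric: str, value: float, sex: Union[Sex, str, None] = None
    ) -> Union[int, str]:
        """Quartile index 1-4, or an out-of-range marker.

        The quartile-4 band of cTnI, the rates and TGI is open above (printed
        as ">x"); LDL and LGI are capped by the exclusion ceiling, above which
        ``"above-range"`` is returned.

        Examples
        --------
        >>> QuartileTable.default().classify("tgr", 1.20)
        2
        >>> QuartileTable.default().classify("tgi", 7.0, "female")
        4
        """
        bands = self.bands_for(metric, sex)
        if value < bands[0].lower:
            return BELOW_RANGE
        if bands[3].upper is not None and value > bands[3].upper:
            return ABOVE_RANGE
        # Gap values (between band k's upper and band k+1's lower printed
        # bound) resolve to the lower band; band 4 starts strictly above
        # band 3's upper edge.
        if value > bands[2].upper:
            return 4
        for k in (1, 2):
            if value < bands[k].lower:
                return k
        return 3

    def describe(self) -> dict[str, list[str]]:
        """Printed-form dump of the table (sex-split cells as 'f/m')."""
        out: dict[str, list[str]] = {}
        for metric in METRIC_NAMES:
            rows = []
            for k in range(4):
                female = self._bands[(metric, Sex.FEMALE)][k]
                male = self._bands[(metric, Sex.MALE)][k]
                if female == male:
                    rows.append(female.describe())
                elif female.upper is None:  # open band, sex-specific lower edge
                    rows.append(f">{female.lower:g}/{male.lower:g}")
                else:
                    rows.append(
                        f"{female.lower:g}–{female.upper:g}/{male.upper:g}"
                    )
            out[metric] = rows
        return out

    def domain(self, metric: str, sex: Union[Sex, str, None] = None) -> tuple[float, float]:
        """(min, max) of the covered range; max is +inf for open band 4."""
        bands = self.bands_for(metric, sex)
        upper = bands[3].upper if bands[3].upper is not None else math.inf
        return bands[0].lower, upper


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of exclusion screening for one panel."""

    checks: dict[str, bool]   # analyte -> passed
    reasons: list[str] = field(default_factory=list)

    @property
    def eligible(self) -> bool:
        return all(self.checks.values())


def screen_exclusions(
    panel: BiomarkerPanel, limits: ExclusionLimits = DEFAULT_LIMITS
) -> ScreenResult:
    """Flag analytes strictly above their exclusion ceilings.

    Screening is total: it never raises on in-range or out-of-range values
    and never mutates the panel.

    Examples
    --------
    >>> import datetime as dt
    >>> p = BiomarkerPanel(dt.date(2024, 1, 1), "male", 5.7, "percent", 240, 5.0, 125)
    >>> screen_exclusions(p).eligible
    True
    """
    ctni_max = (
        limits.ctni_max_female if panel.sex is Sex.FEMALE else limits.ctni_max_male
    )
    checks = {
        "a1c": not panel.a1c_ifcc > limits.a1c_max,
        "ldl": not panel.ldl > limits.ldl_max,
        "ctni": not panel.ctni > ctni_max,
    }
    reasons = []
    if not checks["a1c"]:
        reasons.append(
            f"A1c {panel.a1c_ifcc:g} mmol/mol > {limits.a1c_max:g}: "
            "suggests diabetes mellitus"
        )
    if not checks["ldl"]:
        reasons.append(
            f"LDL {panel.ldl:g} mg/dL > {limits.ldl_max:g}: "
            "suggests severe hyperlipidemia"
        )
    if not checks["ctni"]:
        reasons.append(
            f"cTnI {panel.ctni:g} ng/L > {ctni_max:g} ({panel.sex.value}): "
            "suggests cardiac ischemia or injury"
        )
    return ScreenResult(checks=checks, reasons=reasons)


def calculated_ranges(
    constants: ReferenceConstants = DEFAULT_CONSTANTS,
    limits: ExclusionLimits = DEFAULT_LIMITS,
    rate_max: float = RATE_MAX_DEFAULT,
) -> dict[str, float]:
    """Extremes of the modelled metric ranges.

    The lowest indices pair the optimal rate 1.0 with the concentration
    floors (cTnI detection limit, LDL 60 mg/dL); the highest pair the 1.5
    rate cap with the exclusion ceilings.
    """
    return {
        "rate_min": 1.0,
        "rate_max": rate_max,
        "tgi_min": round_half_up(1.0 * constants.ctni_lod, 1),
        "tgi_max_female": round_half_up(rate_max * limits.ctni_max_female, 2),
        "tgi_max_male": round_half_up(rate_max * limits.ctni_max_male, 2),
        "lgi_min": float(round_half_up(1.0 * constants.ldl_floor, 0)),
        "lgi_max": float(round_half_up(rate_max * limits.ldl_max, 0)),
    }
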