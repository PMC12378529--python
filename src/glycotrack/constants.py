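"""Reference constants of the glycation proxy model.

The model treats pH and temperature as physiologically constant and
characterises each protein by a fixed half-life: A1c 28.7 d, fructosamine
16.5 d, LDL 3 d, cardiac troponin I 1 d.  The glycation optimum is anchored
at A1c 31 mmol/mol (5.0%) with the equivalent fructosamine of 200 µmol/L.
All constants are configuration, not literals: assay- or population-specific
overrides are legitimate (e.g. a cTnI half-life anywhere in the reported
2 h - 3.2 d range), and the dataclasses validate the geometry the
extrapolation depends on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ConfigError


@dataclass(frozen=True)
class ReferenceConstants:
    """Half-lives (days), optimal references and detection floors.

    The half-life ordering A1c > fructosamine > LDL > cTnI is enforced: the
    two glycated-protein anchors must bracket the extrapolation targets from
    above for the two-point line to extrapolate downward in half-life.
    """

    halflife_a1c: float = 28.7
    halflife_fructosamine: float = 16.5
    halflife_ldl: float = 3.0
    halflife_ctni: float = 1.0
    optimal_a1c: float = 31.0        # mmol/mol (IFCC)
    optimal_fructosamine: float = 200.0  # µmol/L
    ctni_lod: float = 1.6            # ng/L, assay limit of detection
    ldl_floor: float = 60.0          # mg/dL, lower bound of the modelled range

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if not value > 0:
                raise ConfigError(f"{field.name} must be positive, got {value!r}")
        if not (
            self.halflife_a1c
            > self.halflife_fructosamine
            > self.halflife_ldl
            > self.halflife_ctni
        ):
            raise ConfigError(
                "half-life ordering must satisfy "
                "A1c > fructosamine > LDL > cTnI, got "
                f"{self.halflife_a1c}/{self.halflife_fructosamine}"
                f"/{self.halflife_ldl}/{self.halflife_ctni}"
            )

    def replace(self, **overrides) -> "ReferenceConstants":
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class ExclusionLimits:
    """Analyte ceilings beyond which the proxy defers to diagnostic work-up.

    A1c above 46 mmol/mol suggests diabetes mellitus, LDL above 180 mg/dL
    severe hyperlipidemia, and cTnI above 4.5 ng/L (women) / 5.0 ng/L (men)
    cardiac ischemia or injury.  The male cTnI ceiling is adjustable in the
    5-7 ng/L range to trade sensitivity for specificity.
    """

    a1c_max: float = 46.0            # mmol/mol
    ldl_max: float = 180.0           # mg/dL
    ctni_max_female: float = 4.5     # ng/L
    ctni_max_male: float = 5.0       # ng/L

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if not value > 0:
                raise ConfigError(f"{field.name} must be positive, got {value!r}")
        if self.ctni_max_male < self.ctni_max_female:
            raise ConfigError(
                "male cTnI limit must be >= female limit, got "
                f"{self.ctni_max_male} < {self.ctni_max_female}"
            )

    def replace(self, **overrides) -> "ExclusionLimits":
        return dataclasses.replace(self, **overrides)


#: Maximum modelled glycation rate (relative to the optimum of 1.0); with the
#: default exclusion ceilings this caps the indices at 6.75/7.5 (TGI, by sex)
#: and 270 (LGI).
RATE_MAX_DEFAULT = 1.5

DEFAULT_CONSTANTS = ReferenceConstants()
DEFAULT_LIMITS = ExclusionLimits()
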