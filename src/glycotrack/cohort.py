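"""Synthetic-cohort generator.

Produces annual biomarker panel series that emulate the two archetypes of
the 30-year comparison — a normoglycemic adult and one drifting into
prediabetes — as linear biomarker drift plus independent Gaussian
measurement noise.  The generator exists so every pipeline stage (metrics,
screening, tracking, burden) is exercisable end-to-end on realistic-shaped
data without any external dataset; it is first-class, seeded and
bit-reproducible.

Archetype biomarker endpoints are chosen so that the *noise-free* year-30
panel reproduces the archetype's published rate endpoints exactly under the
rounding protocol:

* normal: A1c 31 -> 34.4 mmol/mol, fructosamine 200 -> 222 µmol/L
  (rA = rF = 1.11, hence TGR = LGR = 1.11), cTnI 1.6 -> 2.6, LDL 60 -> 100;
* prediabetic: A1c 31 -> 42.8 mmol/mol, fructosamine 200 -> 264 µmol/L
  (rA = 1.38, rF = 1.32, hence TGR = 1.24, LGR = 1.25), cTnI 1.6 -> 3.4,
  LDL 60 -> 140.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, ReferenceConstants
from .errors import ConfigError
from .longitudinal import AnnualSeries, build_series
from .metrics import A1cUnits, BiomarkerPanel, Sex
from .trajectory import ARCHETYPES


@dataclass(frozen=True)
class ArchetypeEndpoints:
    """Start/end biomarker values of one archetype (A1c in mmol/mol)."""

    name: str
    a1c: tuple[float, float]
    fructosamine: tuple[float, float]
    ctni: tuple[float, float]
    ldl: tuple[float, float]


ARCHETYPE_ENDPOINTS = {
    "normal": ArchetypeEndpoints(
        "normal", (31.0, 34.4), (200.0, 222.0), (1.6, 2.6), (60.0, 100.0)
    ),
    "prediabetic": ArchetypeEndpoints(
        "prediabetic", (31.0, 42.8), (200.0, 264.0), (1.6, 3.4), (60.0, 140.0)
    ),
}

#: Conversion factor between A1c noise stated in NGSP % and the IFCC scale.
_PCT_TO_IFCC = 10.93


@dataclass(frozen=True)
class CohortSpec:
    """Size, archetype mixture, noise and cadence of a synthetic cohort.

    Noise standard deviations are per analyte per draw (A1c noise is stated
    in NGSP %-units and scaled to mmol/mol internally); the defaults are
    fixture-scale measurement noise, not literature assay CVs.
    """

    n: int = 100
    weights: dict[str, float] = field(
        default_factory=lambda: {"normal": 0.5, "prediabetic": 0.5}
    )
    sd_a1c_percent: float = 0.1
    sd_fructosamine: float = 5.0   # µmol/L
    sd_ctni: float = 0.2           # ng/L
    sd_ldl: float = 5.0            # mg/dL
    span: float = 30.0             # years
    interval: float = 1.0          # years between draws
    start_year: int = 1990
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"cohort size must be >= 1, got {self.n}")
        if not self.weights:
            raise ConfigError("archetype mixture weights are required")
        for name in self.weights:
            if name not in ARCHETYPE_ENDPOINTS:
                raise ConfigError(
                    f"unknown archetype {name!r}; expected one of {ARCHETYPES}"
                )
        total = sum(self.weights.values())
        if any(w < 0 for w in self.weights.values()) or not math.isclose(
            total, 1.0, rel_tol=0, abs_tol=1e-9
        ):
            raise ConfigError(
                f"mixture weights must be non-negative and sum to 1, got {self.weights}"
            )
        for name in ("sd_a1c_percent", "sd_fructosamine", "sd_ctni", "sd_ldl"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not self.span > 0:
            raise ConfigError("span must be positive")
        if self.interval < 1:
            # series are keyed by calendar year; sub-annual draws would collide
            raise ConfigError(f"interval must be >= 1 year, got {self.interval}")


def _interp(endpoints: tuple[float, float], frac: np.ndarray) -> np.ndarray:
    start, end = endpoints
    return start + (end - start) * frac


def simulate_cohort(
    spec: CohortSpec,
    constants: ReferenceConstants = DEFAULT_CONSTANTS,
) -> list[AnnualSeries]:
    """Generate seeded annual series for ``spec.n`` synthetic individuals.

    Each individual is assigned an archetype from the mixture, a sex
    (balanced Bernoulli), and annual panels whose underlying biomarkers
    interpolate linearly between the archetype's start/end values with
    additive Gaussian noise, truncated away from zero at 10% of the start
    value so panels always validate.  Fixed seed => bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.weights)
    probs = np.array([spec.weights[name] for name in names])
    assignments = rng.choice(len(names), size=spec.n, p=probs)
    sexes = rng.integers(0, 2, size=spec.n)

    n_draws = int(math.floor(spec.span / spec.interval)) + 1
    times = np.arange(n_draws) * spec.interval
    frac = times / spec.span

    sds = {
        "a1c": spec.sd_a1c_percent * _PCT_TO_IFCC,
        "fructosamine": spec.sd_fructosamine,
        "ctni": spec.sd_ctni,
        "ldl": spec.sd_ldl,
    }
    cohort: list[AnnualSeries] = []
    for i in range(spec.n):
        arch = ARCHETYPE_ENDPOINTS[names[assignments[i]]]
        sex = Sex.FEMALE if sexes[i] == 0 else Sex.MALE
        values = {}
        for analyte in ("a1c", "fructosamine", "ctni", "ldl"):
            endpoints = getattr(arch, analyte)
            path = _interp(endpoints, frac)
            noise = rng.normal(0.0, sds[analyte], size=n_draws)
            values[analyte] = np.maximum(path + noise, 0.1 * endpoints[0])
        panels = [
            BiomarkerPanel(
                draw_date=dt.date(spec.start_year + int(math.floor(t)), 6, 1),
                sex=sex,
                a1c=float(values["a1c"][k]),
                a1c_units=A1cUnits.MMOL_MOL,
                fructosamine=float(values["fructosamine"][k]),
                ctni=float(values["ctni"][k]),
                ldl=float(values["ldl"][k]),
            )
            for k, t in enumerate(times)
        ]
        cohort.append(
            build_series(
                panels,
                constants,
                individual_id=f"{arch.name}-{i:04d}",
            )
        )
    return cohort


def series_excess_auc(series: AnnualSeries, index_kind: str = "tgi") -> float:
    """Trapezoidal excess-index AUC of a simulated series above its baseline.

    The baseline is the optimal-reference index (first-draw value in a
    noise-free cohort); negative excursions below baseline contribute zero.
    """
    if index_kind not in ("tgi", "lgi"):
        raise ConfigError(f"index_kind must be 'tgi' or 'lgi', got {index_kind!r}")
    values = np.array(
        [getattr(row.metrics, index_kind) for row in series.rows], dtype=float
    )
    years = np.array(series.years, dtype=float)
    excess = np.maximum(values - values[0], 0.0)
    return float(np.trapezoid(excess, years - years[0]))
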