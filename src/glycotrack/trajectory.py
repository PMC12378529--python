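"""Multi-decade glycation-burden simulation.

Cumulative tissue glycation over a span of years is proxied by the area
under the glycation-index trajectory *above its baseline* — the excess
burden.  The two built-in archetypes compare a normoglycemic adult with one
who drifts into prediabetes over 30 years, both starting at the optimal
references (TGI 1.6, LGI 60 at age 25):

============  =============  ==============  =============  ==============
archetype     TGR (30 y)     cTnI (ng/L)     LGR (30 y)     LDL (mg/dL)
============  =============  ==============  =============  ==============
normal        1.0 -> 1.11    1.6 -> 2.6      1.0 -> 1.11    60 -> 100
prediabetic   1.0 -> 1.24    1.6 -> 3.4      1.0 -> 1.25    60 -> 140
============  =============  ==============  =============  ==============

The index path is linear between the baseline and the endpoint index
(endpoint = rate x concentration, rounded at the index's reporting
precision before integration); an alternative "component-linear" mode
interpolates rate and concentration separately, which yields a quadratic
index path and a slightly smaller burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError, DomainError
from .units import round_half_up, round_half_up_int

ARCHETYPES = ("normal", "prediabetic")
BURDEN_MODES = ("index-linear", "component-linear")

#: Reporting precision (decimal places) per index kind.
_INDEX_PRECISION = {"tgi": 1, "lgi": 0}


@dataclass(frozen=True)
class TrajectorySpec:
    """Endpoints of a rate/concentration drift over a span of years."""

    index_kind: str            # 'tgi' or 'lgi'
    rate_start: float
    rate_end: float
    conc_start: float          # ng/L for TGI, mg/dL for LGI
    conc_end: float
    span: float = 30.0         # years
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.index_kind not in _INDEX_PRECISION:
            raise ConfigError(
                f"index_kind must be 'tgi' or 'lgi', got {self.index_kind!r}"
            )
        if not self.span > 0:
            raise DomainError(f"span must be positive, got {self.span!r}")
        if self.rate_start < 1.0:
            raise DomainError(
                f"start rate must be >= 1.0 (the optimum), got {self.rate_start!r}"
            )
        if not (self.conc_start > 0 and self.conc_end > 0):
            raise DomainError("concentrations must be positive")

    def _round_index(self, value: float) -> float:
        nd = _INDEX_PRECISION[self.index_kind]
        return round_half_up(value, nd) if nd else float(round_half_up_int(value))

    @property
    def baseline_index(self) -> float:
        return self._round_index(self.rate_start * self.conc_start)

    @property
    def endpoint_index(self) -> float:
        return self._round_index(self.rate_end * self.conc_end)


@dataclass(frozen=True)
class BurdenResult:
    """Excess-burden outcome for one trajectory."""

    label: str
    index_kind: str
    baseline: float
    endpoint: float
    auc: float                 # index-units x years above baseline
    span: float


def linear_index_trajectory(
    spec: TrajectorySpec, n_points: int = 301
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the linear index path on a uniform grid over the span.

    The path interpolates in *index space* between the baseline index and
    the endpoint index (rate x concentration rounded at reporting
    precision), so the trapezoidal burden is exactly the triangle
    ``span * (endpoint - baseline) / 2`` for any grid with >= 2 points.
    """
    if n_points < 2:
        raise DomainError(f"n_points must be >= 2, got {n_points}")
    times = np.linspace(0.0, spec.span, n_points)
    values = np.linspace(spec.baseline_index, spec.endpoint_index, n_points)
    return times, values


def component_linear_trajectory(
    spec: TrajectorySpec, n_points: int = 301
) -> tuple[np.ndarray, np.ndarray]:
    """Alternative path: rate and concentration each linear, index = product.

    The product of two linear ramps is quadratic in time, so this mode gives
    a smaller burden than the index-linear path for rising trajectories; it
    is provided for sensitivity analysis, not report reproduction.
    """
    if n_points < 2:
        raise DomainError(f"n_points must be >= 2, got {n_points}")
    times = np.linspace(0.0, spec.span, n_points)
    rate = np.linspace(spec.rate_start, spec.rate_end, n_points)
    conc = np.linspace(spec.conc_start, spec.conc_end, n_points)
    return times, rate * conc


def excess_burden(
    values: np.ndarray,
    baseline: float,
    span: float,
    label: str = "custom",
    index_kind: str = "tgi",
) -> BurdenResult:
    """Trapezoidal integral of max(index - baseline, 0) over the span.

    ``values`` must be sampled on a uniform grid covering [0, span].
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("trajectory is empty")
    if values.size < 2:
        raise DomainError("trajectory needs >= 2 samples for integration")
    if not span > 0:
        raise DomainError(f"span must be positive, got {span!r}")
    times = np.linspace(0.0, span, values.size)
    excess = np.maximum(values - baseline, 0.0)
    auc = float(np.trapezoid(excess, times))
    return BurdenResult(
        label=label,
        index_kind=index_kind,
        baseline=float(baseline),
        endpoint=float(values[-1]),
        auc=auc,
        span=float(span),
    )


def trajectory_burden(
    spec: TrajectorySpec,
    n_points: int = 301,
    mode: str = "index-linear",
) -> BurdenResult:
    """Convenience: sample a spec and integrate its excess burden."""
    if mode not in BURDEN_MODES:
        raise ConfigError(f"burden mode must be one of {BURDEN_MODES}, got {mode!r}")
    sampler = (
        linear_index_trajectory if mode == "index-linear"
        else component_linear_trajectory
    )
    _, values = sampler(spec, n_points)
    return excess_burden(
        values, spec.baseline_index, spec.span,
        label=spec.label, index_kind=spec.index_kind,
    )


@dataclass(frozen=True)
class BurdenComparison:
    ratio: Optional[float]     # None when the reference burden is zero
    narrative: str


def compare_burden(a: BurdenResult, b: BurdenResult) -> BurdenComparison:
    """Burden ratio a/b with a one-decimal "X.X-fold" narrative.

    Requires matching spans and index kinds; a zero reference burden yields
    an undefined-ratio marker rather than an error.
    """
    if a.index_kind != b.index_kind:
        raise ConfigError(
            f"cannot compare {a.index_kind} burden with {b.index_kind} burden"
        )
    if a.span != b.span:
        raise ConfigError(f"cannot compare spans {a.span} and {b.span}")
    if b.auc == 0:
        return BurdenComparison(
            ratio=None,
            narrative=f"undefined ratio: reference burden of {b.label!r} is zero",
        )
    ratio = a.auc / b.auc
    return BurdenComparison(
        ratio=ratio,
        narrative=(
            f"{a.label} accumulated {round_half_up(ratio, 1):.1f}-fold the "
            f"excess {a.index_kind.upper()} burden of {b.label} over "
            f"{a.span:g} years ({a.auc:g}/{b.auc:g})"
        ),
    )


def preset(archetype: str) -> dict[str, TrajectorySpec]:
    """The built-in 30-year archetype endpoints (see module docstring).

    Returns the TGI and LGI specs for ``"normal"`` or ``"prediabetic"``.
    """
    if archetype == "normal":
        return {
            "tgi": TrajectorySpec("tgi", 1.0, 1.11, 1.6, 2.6, 30.0, "normal"),
            "lgi": TrajectorySpec("lgi", 1.0, 1.11, 60.0, 100.0, 30.0, "normal"),
        }
    if archetype == "prediabetic":
        return {
            "tgi": TrajectorySpec("tgi", 1.0, 1.24, 1.6, 3.4, 30.0, "prediabetic"),
            "lgi": TrajectorySpec("lgi", 1.0, 1.25, 60.0, 140.0, 30.0, "prediabetic"),
        }
    raise ConfigError(
        f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}"
    )
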