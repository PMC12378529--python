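"""Sequential annual tracking: report building, forecasting, consistency flags.

A single panel is only one point of reference; the proxy is designed around
*sequential* annual draws.  This module turns a list of dated panels into an
ordered annual series with per-year metrics, forecasts the next year's raw
biomarkers by per-column ordinary least squares on (year index, value), and
annotates biomarker-consistency anomalies:

* glycation gap — a discrepancy between the A1c-implied and the
  fructosamine-implied glycation ratio signals unstable glycemia or assay
  interference;
* divergence — cTnI rising while TGR does not suggests a non-glycation
  cause (e.g. hypertension); cTnI and LDL falling together is the signature
  of an LDL-lowering intervention such as a statin.

Forecasting is deliberately limited to one year ahead: individual biomarker
drift is not stable enough for long-horizon extrapolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, ReferenceConstants
from .errors import InsufficientDataError, ValidationError
from .metrics import (
    A1cUnits,
    BiomarkerPanel,
    GlycationMetrics,
    Sex,
    compute_metrics,
)
from .units import a1c_percent_to_ifcc, round_half_up, round_half_up_int

logger = logging.getLogger(__name__)

#: Default glycation-gap trigger on |rA - rF| (dimensionless ratio units).
#: Not an authorial constant; configurable.
GAP_THRESHOLD_DEFAULT = 0.15

FORECAST_MODES = ("recompute", "column-ols")


@dataclass(frozen=True)
class SeriesRow:
    year: int
    panel: BiomarkerPanel
    metrics: GlycationMetrics


@dataclass(frozen=True)
class AnnualSeries:
    """Chronologically ordered annual panels with derived metrics."""

    rows: tuple[SeriesRow, ...]
    constants: ReferenceConstants = DEFAULT_CONSTANTS
    individual_id: Optional[str] = None

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def years(self) -> list[int]:
        return [row.year for row in self.rows]

    @property
    def sex(self) -> Sex:
        return self.rows[0].panel.sex


@dataclass(frozen=True)
class ForecastRow:
    """One-year-ahead prediction; metrics recomputed from rounded forecasts.

    ``predicted`` is always True — the flag travels with the row so report
    consumers can never mistake a forecast for an observation.
    """

    year: int
    a1c_percent: float
    a1c_mmol_mol: int
    fructosamine: int
    ctni: float
    ldl: int
    metrics: GlycationMetrics
    mode: str = "recompute"
    predicted: bool = True


@dataclass(frozen=True)
class GapFlag:
    """Glycation-gap screen for one panel's metrics."""

    gap: float
    threshold: float
    triggered: bool
    narrative: str


def build_series(
    panels: Sequence[BiomarkerPanel],
    constants: ReferenceConstants = DEFAULT_CONSTANTS,
    individual_id: Optional[str] = None,
) -> AnnualSeries:
    """Sort panels chronologically, compute metrics, validate annual cadence.

    Duplicate calendar years are rejected; gaps longer than one year are
    tolerated but logged, since infrequent or delayed monitoring degrades
    the sequential analysis the proxy depends on.
    """
    if not panels:
        raise ValidationError("at least one panel is required")
    ordered = sorted(panels, key=lambda p: p.draw_date)
    years = [p.year for p in ordered]
    seen: dict[int, BiomarkerPanel] = {}
    for p in ordered:
        if p.year in seen:
            raise ValidationError(f"duplicate year {p.year} in panel series")
        seen[p.year] = p
    for prev, nxt in zip(years, years[1:]):
        if nxt - prev > 1:
            logger.warning(
                "gap of %d years between %d and %d: infrequent monitoring "
                "can lead to inaccuracies",
                nxt - prev, prev, nxt,
            )
    rows = tuple(
        SeriesRow(year=p.year, panel=p, metrics=compute_metrics(p, constants))
        for p in ordered
    )
    return AnnualSeries(rows=rows, constants=constants, individual_id=individual_id)


def _ols_predict(y: Sequence[float], x_next: float) -> float:
    """Least-squares line through (0..n-1, y) evaluated at ``x_next``."""
    x = np.arange(len(y), dtype=float)
    slope, intercept = np.polyfit(x, np.asarray(y, dtype=float), 1)
    return float(slope * x_next + intercept)


def forecast_next(
    series: AnnualSeries,
    mode: str = "recompute",
) -> ForecastRow:
    """Predict next year's biomarkers by per-column OLS; derive the metrics.

    Each raw biomarker column (A1c on the percent scale, fructosamine, cTnI,
    LDL) is fitted by ordinary least squares against the 0-based year index
    and evaluated one year ahead; calendar-day spacing within a year is
    ignored (annual cadence).  Predictions are rounded to the column's
    reporting precision *first* (A1c 1 dp, fructosamine and LDL integer,
    cTnI 1 dp), then the glycation metrics are recomputed from the rounded
    forecasts so the predicted row satisfies the same internal identities as
    observed rows.  ``mode="column-ols"`` instead extrapolates the metric
    columns themselves (each rounded at its own precision).
    """
    if mode not in FORECAST_MODES:
        raise ValidationError(
            f"forecast mode must be one of {FORECAST_MODES}, got {mode!r}"
        )
    if len(series) < 2:
        raise InsufficientDataError(
            f"forecasting requires >= 2 observations, got {len(series)}"
        )
    x_next = float(len(series))
    rows = series.rows
    a1c_pred = round_half_up(
        _ols_predict([r.panel.a1c_percent for r in rows], x_next), 1
    )
    fruct_pred = round_half_up_int(
        _ols_predict([r.panel.fructosamine for r in rows], x_next)
    )
    ctni_pred = round_half_up(_ols_predict([r.panel.ctni for r in rows], x_next), 1)
    ldl_pred = round_half_up_int(_ols_predict([r.panel.ldl for r in rows], x_next))

    predicted_panel = BiomarkerPanel(
        draw_date=rows[-1].panel.draw_date.replace(year=rows[-1].year + 1),
        sex=series.sex,
        a1c=a1c_pred,
        a1c_units=A1cUnits.PERCENT,
        fructosamine=fruct_pred,
        ctni=ctni_pred,
        ldl=ldl_pred,
    )
    metrics = compute_metrics(predicted_panel, series.constants)
    if mode == "column-ols":
        tgr = round_half_up(_ols_predict([r.metrics.tgr for r in rows], x_next), 2)
        lgr = round_half_up(_ols_predict([r.metrics.lgr for r in rows], x_next), 2)
        metrics = GlycationMetrics(
            ratio_a1c=metrics.ratio_a1c,
            ratio_fructosamine=metrics.ratio_fructosamine,
            slope=metrics.slope,
            intercept=metrics.intercept,
            tgr=tgr,
            lgr=lgr,
            tgi=round_half_up(tgr * ctni_pred, 1),
            lgi=round_half_up_int(lgr * ldl_pred),
        )
    return ForecastRow(
        year=rows[-1].year + 1,
        a1c_percent=a1c_pred,
        a1c_mmol_mol=a1c_percent_to_ifcc(a1c_pred),
        fructosamine=fruct_pred,
        ctni=ctni_pred,
        ldl=ldl_pred,
        metrics=metrics,
        mode=mode,
    )


def glycation_gap(
    metrics: GlycationMetrics,
    threshold: float = GAP_THRESHOLD_DEFAULT,
) -> GapFlag:
    """Flag a discrepancy between A1c- and fructosamine-implied glycation.

    Triggered when ``|rA - rF|`` exceeds the threshold; the narrative names
    the dominant analyte so the reviewing clinician knows which way the
    discrepancy points (unstable glycemia, recent weight or medication
    change, assay interference).
    """
    gap = metrics.glycation_gap
    triggered = abs(gap) > threshold
    if not triggered:
        narrative = f"glycation gap {gap:+.2f} within ±{threshold:g}"
    elif gap > 0:
        narrative = (
            f"glycation gap {gap:+.2f} exceeds ±{threshold:g}: A1c-implied "
            "glycation dominates (suggests recent glucose decline or A1c "
            "interference)"
        )
    else:
        narrative = (
            f"glycation gap {gap:+.2f} exceeds ±{threshold:g}: "
            "fructosamine-implied glycation dominates (suggests recent "
            "glucose rise or fructosamine interference)"
        )
    return GapFlag(gap=gap, threshold=threshold, triggered=triggered,
                   narrative=narrative)


@dataclass(frozen=True)
class Annotation:
    year_from: int
    year_to: int
    kind: str
    text: str


def divergence_note(series: AnnualSeries) -> list[Annotation]:
    """Annotate year-over-year cTnI/TGR (and cTnI/LDL) co-movement.

    A parallel rise of TGR and cTnI points at glycation as the driver of the
    troponin change; cTnI rising while TGR is flat or falling points at a
    non-glycation factor (e.g. hypertension); cTnI and LDL falling together
    is consistent with an LDL-lowering intervention.
    """
    if len(series) < 2:
        raise InsufficientDataError(
            f"divergence annotation requires >= 2 observations, got {len(series)}"
        )
    notes: list[Annotation] = []
    for prev, nxt in zip(series.rows, series.rows[1:]):
        d_tgr = nxt.metrics.tgr - prev.metrics.tgr
        d_ctni = nxt.panel.ctni - prev.panel.ctni
        d_ldl = nxt.panel.ldl - prev.panel.ldl
        span = (prev.year, nxt.year)
        if d_ctni > 0 and d_tgr > 0:
            notes.append(Annotation(
                *span, "parallel increase",
                f"{prev.year}->{nxt.year}: TGR {d_tgr:+.2f} with cTnI "
                f"{d_ctni:+.1f} ng/L — parallel increase, glycation-consistent",
            ))
        elif d_ctni > 0:
            notes.append(Annotation(
                *span, "non-glycation factor suspected",
                f"{prev.year}->{nxt.year}: cTnI {d_ctni:+.1f} ng/L without a "
                "TGR increase — non-glycation factor suspected",
            ))
        if d_ctni < 0 and d_ldl < 0:
            notes.append(Annotation(
                *span, "consistent with LDL-lowering intervention",
                f"{prev.year}->{nxt.year}: cTnI {d_ctni:+.1f} ng/L and LDL "
                f"{d_ldl:+.0f} mg/dL both falling — consistent with "
                "LDL-lowering intervention",
            ))
    return notes
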