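"""Annual series construction, OLS forecasting, consistency flags."""

import datetime as dt
import logging
import random

import numpy as np
import pytest

from glycotrack import (
    InsufficientDataError,
    ValidationError,
    build_series,
    compute_metrics,
    divergence_note,
    forecast_next,
    glycation_gap,
)
from glycotrack.longitudinal import _ols_predict
from glycotrack.units import round_half_up, round_half_up_int

from conftest import make_panel


def test_build_series_metric_columns(report_panels):
    series = build_series(report_panels)
    assert [row.metrics.tgi for row in series.rows] == [2.9, 3.3, 3.6, 4.3]
    assert [row.metrics.tgr for row in series.rows] == [1.10, 1.10, 1.12, 1.26]
    assert series.years == [2022, 2023, 2024, 2025]


def test_single_panel_series(report_panels):
    series = build_series(report_panels[:1])
    assert len(series) == 1
    with pytest.raises(InsufficientDataError):
        forecast_next(series)


def test_sorting_invariance(report_panels):
    shuffled = list(report_panels)
    random.Random(3).shuffle(shuffled)
    assert build_series(shuffled).rows == build_series(report_panels).rows


def test_duplicate_years_rejected(report_panels):
    with pytest.raises(ValidationError, match="2022"):
        build_series(report_panels + [make_panel("2022-12-01", 5.6, 235, 2.7, 112)])


def test_monitoring_gap_logged(report_panels, caplog):
    gapped = [report_panels[0], make_panel("2025-06-01", 6.0, 262, 3.4, 130)]
    with caplog.at_level(logging.WARNING, logger="glycotrack.longitudinal"):
        build_series(gapped)
    assert any("gap of 3 years" in message for message in caplog.messages)


def test_forecast_reproduces_report_row(report_panels):
    """2026 predictions from per-column OLS on the four observed years."""
    forecast = forecast_next(build_series(report_panels))
    assert forecast.year == 2026
    assert forecast.a1c_percent == 6.1
    assert forecast.a1c_mmol_mol == 43
    assert forecast.fructosamine == 267
    assert forecast.ctni == 3.7
    assert forecast.predicted is True
    # the LDL column extrapolates to exactly 137.5; the printed report
    # rounds it to 137
    unrounded = _ols_predict([p.ldl for p in report_panels], 4.0)
    assert unrounded == pytest.approx(137.5, abs=1e-9)
    assert abs(forecast.ldl - 137.5) <= 0.5


def test_forecast_metrics_recomputed_from_rounded_biomarkers(report_panels):
    forecast = forecast_next(build_series(report_panels))
    m = forecast.metrics
    assert m.tgi == round_half_up(m.tgr * forecast.ctni, 1)
    assert m.lgi == round_half_up_int(m.lgr * forecast.ldl)


def test_forecast_exact_line():
    """OLS reproduces a perfectly linear column exactly."""
    panels = [
        make_panel(f"{2020 + k}-06-01", 5.0 + 0.2 * k, 200 + 10 * k,
                   1.6 + 0.3 * k, 60 + 5 * k)
        for k in range(3)
    ]
    forecast = forecast_next(build_series(panels))
    assert forecast.a1c_percent == pytest.approx(5.6)
    assert forecast.fructosamine == 230
    assert forecast.ctni == pytest.approx(2.5)
    assert forecast.ldl == 75


def test_forecast_consistency_preserves_linearity():
    """Appending the forecast of an exactly linear series keeps it linear."""
    panels = [
        make_panel(f"{2020 + k}-06-01", 5.0 + 0.1 * k, 200 + 8 * k,
                   2.0 + 0.2 * k, 80 + 4 * k)
        for k in range(4)
    ]
    first = forecast_next(build_series(panels))
    extended = panels + [
        make_panel("2024-06-01", first.a1c_percent, first.fructosamine,
                   first.ctni, first.ldl)
    ]
    second = forecast_next(build_series(extended))
    assert second.fructosamine == 240
    assert second.ldl == 100
    assert second.ctni == pytest.approx(3.0)


def test_ols_oracle_normal_equations():
    """np.polyfit forecasts agree with the normal-equations closed form."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = rng.integers(3, 11)
        y = rng.normal(100, 20, size=n)
        x = np.arange(n, dtype=float)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        expected = slope * n + intercept
        assert _ols_predict(list(y), float(n)) == pytest.approx(expected, abs=1e-10)


def test_ols_oracle_statsmodels(report_panels):
    """Cross-check the fructosamine forecast against statsmodels OLS."""
    sm = pytest.importorskip("statsmodels.api")
    y = np.array([p.fructosamine for p in report_panels], dtype=float)
    x = sm.add_constant(np.arange(len(y), dtype=float))
    fitted = sm.OLS(y, x).fit()
    expected = float(fitted.params[0] + fitted.params[1] * len(y))
    assert _ols_predict(list(y), float(len(y))) == pytest.approx(expected, abs=1e-8)
    assert round_half_up_int(expected) == 267


def test_column_ols_mode(report_panels):
    """The alternative mode extrapolates the metric columns directly."""
    series = build_series(report_panels)
    recompute = forecast_next(series, mode="recompute")
    column = forecast_next(series, mode="column-ols")
    assert column.fructosamine == recompute.fructosamine  # biomarkers shared
    tgr_pred = _ols_predict([r.metrics.tgr for r in series.rows], 4.0)
    assert column.metrics.tgr == round_half_up(tgr_pred, 2)
    with pytest.raises(ValidationError):
        forecast_next(series, mode="bogus")


def test_permutation_invariance(report_panels):
    series = build_series(report_panels)
    for seed in (1, 2, 3):
        shuffled = list(report_panels)
        random.Random(seed).shuffle(shuffled)
        other = forecast_next(build_series(shuffled))
        assert other == forecast_next(series)


@pytest.mark.parametrize(
    ("ra", "rf", "threshold", "triggered"),
    [(1.26, 1.20, 0.15, False), (1.00, 1.00, 0.15, False),
     (1.40, 1.15, 0.15, True), (1.10, 1.30, 0.15, True)],
)
def test_glycation_gap(ra, rf, threshold, triggered, optimum_panel):
    metrics = compute_metrics(optimum_panel)
    metrics = type(metrics)(
        ratio_a1c=ra, ratio_fructosamine=rf, slope=0.0, intercept=1.0,
        tgr=1.0, lgr=1.0, tgi=1.6, lgi=60,
    )
    flag = glycation_gap(metrics, threshold)
    assert flag.gap == pytest.approx(ra - rf)
    assert flag.triggered is triggered
    assert flag.triggered == (abs(ra - rf) > threshold)
    if triggered:
        dominant = "A1c" if ra > rf else "fructosamine"
        assert dominant in flag.narrative


def test_divergence_annotations(report_panels):
    notes = divergence_note(build_series(report_panels))
    kinds = {(n.year_from, n.year_to): n.kind for n in notes}
    # 2022->2023: cTnI rose while TGR stayed at 1.10
    assert kinds[(2022, 2023)] == "non-glycation factor suspected"
    assert kinds[(2024, 2025)] == "parallel increase"


def test_divergence_statin_pattern():
    panels = [
        make_panel("2022-06-01", 5.7, 240, 3.4, 130),
        make_panel("2023-06-01", 5.7, 240, 3.0, 110),  # cTnI and LDL both fall
    ]
    notes = divergence_note(build_series(panels))
    assert [n.kind for n in notes] == ["consistent with LDL-lowering intervention"]


def test_divergence_flat_series_silent():
    panels = [
        make_panel("2022-06-01", 5.7, 240, 3.2, 125),
        make_panel("2023-06-01", 5.7, 240, 3.2, 125),
    ]
    assert divergence_note(build_series(panels)) == []
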