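"""Concentration ratios, slope-intercept extrapolation, metric derivation."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycotrack import (
    BiomarkerPanel,
    DegenerateGeometryError,
    DomainError,
    ReferenceConstants,
    ValidationError,
    compute_metrics,
    concentration_ratio,
    rate_at_halflife,
    slope_intercept,
)
from glycotrack.constants import DEFAULT_CONSTANTS
from glycotrack.errors import ConfigError

from conftest import make_panel


@pytest.mark.parametrize(
    ("observed", "optimal", "expected"),
    [(39, 31, 1.26), (240, 200, 1.20), (200, 200, 1.00), (42, 31, 1.35),
     (262, 200, 1.31)],
)
def test_concentration_ratio_examples(observed, optimal, expected):
    assert concentration_ratio(observed, optimal) == expected


@pytest.mark.parametrize(("observed", "optimal"), [(39, 0), (39, -1), (0, 31)])
def test_concentration_ratio_domain(observed, optimal):
    with pytest.raises(DomainError):
        concentration_ratio(observed, optimal)


@pytest.mark.parametrize(
    ("ra", "rf", "halflife", "expected"),
    [
        (1.26, 1.20, 1, 1.12),   # troponin glycation rate, worked example
        (1.26, 1.20, 3, 1.13),   # LDL glycation rate, worked example
        (1.00, 1.00, 1, 1.00),   # flat line through both anchors
        (1.35, 1.31, 1, 1.26),   # 2025 report row
        (1.35, 1.31, 3, 1.27),
    ],
)
def test_rate_at_halflife_examples(ra, rf, halflife, expected):
    assert rate_at_halflife(ra, rf, halflife) == expected


def test_worked_example_slope_intercept():
    m, b = slope_intercept(1.26, 1.20)
    assert round(m, 4) == 0.0049
    assert round(b, 2) == 1.12


def test_degenerate_anchor_geometry():
    with pytest.raises(ConfigError):
        # equal anchor half-lives are rejected at construction
        ReferenceConstants(halflife_a1c=16.5, halflife_fructosamine=16.5)
    with pytest.raises(DegenerateGeometryError):

        class _Broken:
            halflife_a1c = 16.5
            halflife_fructosamine = 16.5

        slope_intercept(1.26, 1.20, _Broken())


def test_nonpositive_target_halflife():
    with pytest.raises(DomainError):
        rate_at_halflife(1.26, 1.20, 0)


def test_slope_intercept_reproduces_anchors():
    m, b = slope_intercept(1.26, 1.20)
    c = DEFAULT_CONSTANTS
    assert m * c.halflife_a1c + b == pytest.approx(1.26, abs=1e-12)
    assert m * c.halflife_fructosamine + b == pytest.approx(1.20, abs=1e-12)


def test_closed_form_oracle_equivalence():
    """Slope-intercept procedure == two-point interpolation closed form.

    For 10^4 random ratio pairs the unrounded extrapolation must match
    rF + (rA - rF)(h - 16.5)/12.2 to 1e-12 at both target half-lives.
    """
    rng = np.random.default_rng(20240601)
    c = DEFAULT_CONSTANTS
    pairs = rng.uniform(0.8, 2.0, size=(10_000, 2))
    for h in (c.halflife_ctni, c.halflife_ldl):
        for ra, rf in pairs:
            m, b = slope_intercept(ra, rf)
            closed = rf + (ra - rf) * (h - 16.5) / 12.2
            assert abs((m * h + b) - closed) < 1e-12


def test_weighted_combination_identity():
    """Unrounded rates are fixed affine combinations of the two ratios.

    TGR = ((28.7-1)/12.2) rF - ((16.5-1)/12.2) rA and analogously for LGR at
    h = 3; each coefficient pair sums to 1.
    """
    rng = np.random.default_rng(7)
    for h, name in ((1.0, "tgr"), (3.0, "lgr")):
        w_f = (28.7 - h) / 12.2
        w_a = -(16.5 - h) / 12.2
        assert w_f + w_a == pytest.approx(1.0, abs=1e-12)
        for ra, rf in rng.uniform(0.8, 2.0, size=(100, 2)):
            m, b = slope_intercept(ra, rf)
            assert m * h + b == pytest.approx(w_f * rf + w_a * ra, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(
    ra=st.floats(min_value=0.8, max_value=2.0),
    rf=st.floats(min_value=0.8, max_value=2.0),
)
def test_rate_difference_and_ordering(ra, rf):
    """LGR - TGR = 2m unrounded; TGR <= LGR iff rA >= rF."""
    m, b = slope_intercept(ra, rf)
    tgr_u = m * 1.0 + b
    lgr_u = m * 3.0 + b
    assert lgr_u - tgr_u == pytest.approx(2 * m, abs=1e-12)
    if ra >= rf:
        assert tgr_u <= lgr_u + 1e-15
    else:
        assert tgr_u >= lgr_u - 1e-15


def test_monotonicity_in_each_ratio():
    """Unrounded TGR rises strictly in rF and falls strictly in rA.

    Extrapolating below both anchors weights the shorter-half-life anchor
    positively (coefficient > 1) and the longer one negatively.
    """
    grid = np.linspace(0.9, 1.6, 15)
    for h in (1.0, 3.0):
        fixed_ra = [slope_intercept(1.2, rf)[0] * h + slope_intercept(1.2, rf)[1]
                    for rf in grid]
        assert all(np.diff(fixed_ra) > 0)
        fixed_rf = [slope_intercept(ra, 1.2)[0] * h + slope_intercept(ra, 1.2)[1]
                    for ra in grid]
        assert all(np.diff(fixed_rf) < 0)


@pytest.mark.parametrize(
    ("a1c", "units", "fruct", "ctni", "ldl", "field", "expected"),
    [
        (39, "mmol/mol", 240, 3.2, 125, "tgi", 3.6),
        (42, "mmol/mol", 262, 3.4, 130, "lgi", 165),
        (5.7, "percent", 240, 3.2, 125, "tgr", 1.12),
        (5.7, "percent", 240, 3.2, 125, "lgr", 1.13),
    ],
)
def test_compute_metrics_examples(a1c, units, fruct, ctni, ldl, field, expected):
    panel = BiomarkerPanel(dt.date(2024, 6, 1), "male", a1c, units, fruct, ctni, ldl)
    assert getattr(compute_metrics(panel), field) == expected


def test_identity_at_optimum(optimum_panel):
    """A panel at the optimal references has all rates 1.0 and raw indices."""
    m = compute_metrics(optimum_panel)
    assert (m.tgr, m.lgr) == (1.0, 1.0)
    assert m.tgi == 1.6
    assert m.lgi == 60
    assert m.slope == 0.0


def test_index_rounding_identities(report_panels):
    """TGI/LGI always equal the rounded rate-times-concentration products."""
    from glycotrack.units import round_half_up, round_half_up_int

    for panel in report_panels:
        m = compute_metrics(panel)
        assert m.tgi == round_half_up(m.tgr * panel.ctni, 1)
        assert m.lgi == round_half_up_int(m.lgr * panel.ldl)
        assert isinstance(m.lgi, int)


def test_panel_validation():
    with pytest.raises(ValidationError):
        make_panel("2024-01-01", 5.7, -240, 3.2, 125)
    with pytest.raises(ValidationError):
        BiomarkerPanel(dt.date(2024, 1, 1), "other", 5.7, "percent", 240, 3.2, 125)
    with pytest.raises(ValidationError):
        BiomarkerPanel(dt.date(2024, 1, 1), "male", 5.7, "mol", 240, 3.2, 125)


def test_a1c_units_never_inferred():
    """39 tagged percent is 39% NGSP, not 39 mmol/mol."""
    as_ifcc = BiomarkerPanel(
        dt.date(2024, 1, 1), "male", 39, "mmol/mol", 240, 3.2, 125
    )
    as_percent = BiomarkerPanel(
        dt.date(2024, 1, 1), "male", 39, "percent", 240, 3.2, 125
    )
    assert as_ifcc.a1c_ifcc == 39
    assert as_percent.a1c_ifcc == pytest.approx(403)  # 10.93*39 - 23.5, rounded


def test_unit_equivalence_of_tagged_panels(worked_example_panel):
    """5.7% and 39 mmol/mol produce identical metrics."""
    ifcc_panel = BiomarkerPanel(
        worked_example_panel.draw_date, "male", 39, "mmol/mol", 240, 3.2, 125
    )
    assert compute_metrics(ifcc_panel) == compute_metrics(worked_example_panel)
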