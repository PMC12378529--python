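"""Model/Results interface over the tracking pipeline.

:class:`GlycationModel` is built from one individual's dated biomarker
panels (objects, a DataFrame, or a CSV file); :meth:`GlycationModel.fit`
computes the per-year glycation metrics, the one-year OLS forecast, the
quartile assignments, exclusion screens, glycation-gap flags and divergence
annotations, and returns a :class:`GlycationResults` whose ``summary()``
renders the annual report table.

Example
-------
>>> import datetime as dt
>>> from glycotrack import BiomarkerPanel, GlycationModel
>>> panels = [
...     BiomarkerPanel(dt.date(2024, 5, 1), "male", 5.7, "percent", 240, 3.2, 125),
...     BiomarkerPanel(dt.date(2025, 5, 1), "male", 6.0, "percent", 262, 3.4, 130),
... ]
>>> res = GlycationModel(panels).fit()
>>> res.forecast.fructosamine
284
"""

from __future__ import annotations

import io as _io
from typing import Optional, Sequence, Union

import pandas as pd

from .classify import (
    DEFAULT_LIMITS,
    ExclusionLimits,
    QuartileTable,
    ScreenResult,
    screen_exclusions,
)
from .constants import DEFAULT_CONSTANTS, ReferenceConstants
from .errors import ValidationError
from .longitudinal import (
    GAP_THRESHOLD_DEFAULT,
    Annotation,
    AnnualSeries,
    ForecastRow,
    GapFlag,
    build_series,
    divergence_note,
    forecast_next,
    glycation_gap,
)
from .metrics import BiomarkerPanel

REPORT_COLUMNS = [
    "year", "a1c_percent", "a1c_mmol_mol", "fructosamine", "ctni",
    "tgr", "tgi", "ldl", "lgr", "lgi", "predicted",
]


class GlycationModel:
    """Glycation-proxy tracking model for one individual's panel series.

    Parameters
    ----------
    panels : sequence of BiomarkerPanel
        One or more dated draws for the same individual (same sex).
    constants : ReferenceConstants, optional
        Half-lives, optimal references and floors; defaults to the published
        constants.
    limits : ExclusionLimits, optional
        Screening ceilings; defaults to A1c 46 mmol/mol, LDL 180 mg/dL,
        cTnI 4.5/5.0 ng/L by sex.
    quartiles : QuartileTable, optional
        Banding table; derived from ``limits`` by default.
    """

    def __init__(
        self,
        panels: Sequence[BiomarkerPanel],
        constants: ReferenceConstants = DEFAULT_CONSTANTS,
        limits: ExclusionLimits = DEFAULT_LIMITS,
        quartiles: Optional[QuartileTable] = None,
        individual_id: Optional[str] = None,
    ):
        if not panels:
            raise ValidationError("at least one panel is required")
        sexes = {p.sex for p in panels}
        if len(sexes) > 1:
            raise ValidationError(
                f"panels mix sexes {sorted(s.value for s in sexes)}; "
                "a model tracks one individual"
            )
        self.panels = list(panels)
        self.constants = constants
        self.limits = limits
        self.quartiles = quartiles or QuartileTable.default(limits, constants)
        self.individual_id = individual_id

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GlycationModel":
        """Build from a DataFrame with columns
        date, sex, a1c, a1c_units, fructosamine, ctni, ldl."""
        required = {"date", "sex", "a1c", "a1c_units", "fructosamine", "ctni", "ldl"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        panels = [
            BiomarkerPanel(
                draw_date=str(row["date"]),
                sex=row["sex"],
                a1c=float(row["a1c"]),
                a1c_units=row["a1c_units"],
                fructosamine=float(row["fructosamine"]),
                ctni=float(row["ctni"]),
                ldl=float(row["ldl"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(panels, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GlycationModel":
        from .io import read_panels_csv

        return cls(read_panels_csv(path), **kwargs)

    def fit(
        self,
        forecast_mode: str = "recompute",
        gap_threshold: float = GAP_THRESHOLD_DEFAULT,
    ) -> "GlycationResults":
        """Compute metrics, forecast, screens and flags.

        A single-panel model fits without a forecast (``results.forecast`` is
        None); forecasting needs at least two annual observations.
        """
        series = build_series(
            self.panels, self.constants, individual_id=self.individual_id
        )
        forecast = forecast_next(series, mode=forecast_mode) if len(series) >= 2 else None
        gaps = {
            row.year: glycation_gap(row.metrics, gap_threshold)
            for row in series.rows
        }
        screens = {
            row.year: screen_exclusions(row.panel, self.limits)
            for row in series.rows
        }
        annotations = divergence_note(series) if len(series) >= 2 else []
        return GlycationResults(
            model=self,
            series=series,
            forecast=forecast,
            gap_flags=gaps,
            screens=screens,
            annotations=annotations,
        )


class GlycationResults:
    """Fitted tracking results: annual report, forecast and diagnostics."""

    def __init__(
        self,
        model: GlycationModel,
        series: AnnualSeries,
        forecast: Optional[ForecastRow],
        gap_flags: dict[int, GapFlag],
        screens: dict[int, ScreenResult],
        annotations: list[Annotation],
    ):
        self.model = model
        self.series = series
        self.forecast = forecast
        self.gap_flags = gap_flags
        self.screens = screens
        self.annotations = annotations

    @property
    def frame(self) -> pd.DataFrame:
        """Annual report in the standard layout, forecast row flagged."""
        records = []
        for row in self.series.rows:
            p, m = row.panel, row.metrics
            records.append({
                "year": row.year,
                "a1c_percent": p.a1c_percent,
                "a1c_mmol_mol": int(p.a1c_ifcc) if float(p.a1c_ifcc).is_integer()
                else p.a1c_ifcc,
                "fructosamine": p.fructosamine,
                "ctni": p.ctni,
                "tgr": m.tgr,
                "tgi": m.tgi,
                "ldl": p.ldl,
                "lgr": m.lgr,
                "lgi": m.lgi,
                "predicted": False,
            })
        if self.forecast is not None:
            f = self.forecast
            records.append({
                "year": f.year,
                "a1c_percent": f.a1c_percent,
                "a1c_mmol_mol": f.a1c_mmol_mol,
                "fructosamine": f.fructosamine,
                "ctni": f.ctni,
                "tgr": f.metrics.tgr,
                "tgi": f.metrics.tgi,
                "ldl": f.ldl,
                "lgr": f.metrics.lgr,
                "lgi": f.metrics.lgi,
                "predicted": True,
            })
        frame = pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)
        return frame.astype({
            "year": "int64",
            "a1c_percent": float, "a1c_mmol_mol": float, "fructosamine": float,
            "ctni": float, "tgr": float, "tgi": float, "ldl": float,
            "lgr": float, "lgi": "int64", "predicted": bool,
        })

    def quartiles(self, year: Optional[int] = None) -> dict[str, Union[int, str]]:
        """Quartile assignment of every biomarker/metric for one year
        (latest observed year by default)."""
        years = self.series.years
        year = years[-1] if year is None else year
        row = next((r for r in self.series.rows if r.year == year), None)
        if row is None:
            raise ValidationError(f"no observation for year {year}")
        sex = self.series.sex
        table = self.model.quartiles
        return {
            "ctni": table.classify("ctni", row.panel.ctni, sex),
            "tgr": table.classify("tgr", row.metrics.tgr),
            "tgi": table.classify("tgi", row.metrics.tgi, sex),
            "ldl": table.classify("ldl", row.panel.ldl),
            "lgr": table.classify("lgr", row.metrics.lgr),
            "lgi": table.classify("lgi", row.metrics.lgi),
        }

    @property
    def eligible(self) -> bool:
        """True when every observed panel passes exclusion screening."""
        return all(screen.eligible for screen in self.screens.values())

    def to_csv(self, path_or_buf) -> None:
        self.frame.to_csv(path_or_buf, index=False)

    def summary(self) -> str:
        """Plain-text annual report with diagnostics."""
        buf = _io.StringIO()
        ident = self.series.individual_id or "individual"
        buf.write(f"Glycation tracking report — {ident} ({self.series.sex.value})\n")
        c = self.series.constants
        buf.write(
            "constants: half-lives "
            f"A1c {c.halflife_a1c:g} d, fructosamine {c.halflife_fructosamine:g} d, "
            f"LDL {c.halflife_ldl:g} d, cTnI {c.halflife_ctni:g} d; optima "
            f"A1c {c.optimal_a1c:g} mmol/mol, fructosamine "
            f"{c.optimal_fructosamine:g} µmol/L\n\n"
        )
        buf.write(self.frame.to_string(index=False))
        buf.write("\n")
        if self.forecast is None:
            buf.write(
                "\nno forecast: a single determination is inadequate; "
                "sequential annual panels are required\n"
            )
        failing = {y: s for y, s in self.screens.items() if not s.eligible}
        if failing:
            buf.write("\nexclusion screening:\n")
            for year, screen in failing.items():
                for reason in screen.reasons:
                    buf.write(f"  {year}: {reason}\n")
        triggered = {y: g for y, g in self.gap_flags.items() if g.triggered}
        if triggered:
            buf.write("\nglycation-gap flags:\n")
            for year, flag in triggered.items():
                buf.write(f"  {year}: {flag.narrative}\n")
        if self.annotations:
            buf.write("\nannotations:\n")
            for note in self.annotations:
                buf.write(f"  {note.text}\n")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<GlycationResults: {len(self.series)} years, "
            f"forecast={'yes' if self.forecast else 'no'}>"
        )
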