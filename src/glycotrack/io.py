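"""CSV and configuration I/O.

One flat CSV dialect (comma, UTF-8, header required, ISO dates) — the
tool's inputs are laboratory spreadsheets.  Input header::

    date,sex,a1c,a1c_units,fructosamine,ctni,ldl

Sex is required per row because the cTnI/TGI limits are sex-specific; rows
that fail validation are reported with their line number and skipped, and
only an all-rows-invalid file is a hard error.

Configuration is a flat key/value file (YAML mapping, no nesting) covering
constant overrides, exclusion limits, the forecast and burden modes and the
glycation-gap threshold.  Unspecified keys fall back to the built-in
defaults; the effective configuration is echoed to the log so default vs
override is auditable.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .constants import DEFAULT_CONSTANTS, DEFAULT_LIMITS, ExclusionLimits, ReferenceConstants
from .errors import ConfigError, ValidationError
from .longitudinal import FORECAST_MODES, GAP_THRESHOLD_DEFAULT
from .metrics import BiomarkerPanel
from .trajectory import BURDEN_MODES

logger = logging.getLogger(__name__)

CSV_HEADER = ["date", "sex", "a1c", "a1c_units", "fructosamine", "ctni", "ldl"]


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


def read_panels_csv(
    path, on_error: str = "raise"
) -> Union[list[BiomarkerPanel], tuple[list[BiomarkerPanel], list[RowError]]]:
    """Read biomarker panels from a CSV file.

    ``on_error="raise"`` raises :class:`ValidationError` on the first bad
    row; ``on_error="collect"`` returns ``(panels, row_errors)`` and raises
    only if *every* row is invalid.
    """
    if on_error not in ("raise", "collect"):
        raise ConfigError(f"on_error must be 'raise' or 'collect', got {on_error!r}")
    panels: list[BiomarkerPanel] = []
    errors: list[RowError] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, header required")
        missing = set(CSV_HEADER) - set(reader.fieldnames)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for record in reader:
            line = reader.line_num
            try:
                if not (record.get("sex") or "").strip():
                    raise ValidationError("sex is required and has no default")
                panels.append(BiomarkerPanel(
                    draw_date=(record["date"] or "").strip(),
                    sex=record["sex"],
                    a1c=float(record["a1c"]),
                    a1c_units=record["a1c_units"],
                    fructosamine=float(record["fructosamine"]),
                    ctni=float(record["ctni"]),
                    ldl=float(record["ldl"]),
                ))
            except (ValidationError, ValueError, KeyError, TypeError) as exc:
                message = f"{path}:{line}: {exc}"
                if on_error == "raise":
                    raise ValidationError(message) from exc
                logger.warning("skipping bad row %s", message)
                errors.append(RowError(line=line, message=message))
    if on_error == "collect":
        if errors and not panels:
            raise ValidationError(f"{path}: all rows invalid ({len(errors)} errors)")
        return panels, errors
    if not panels:
        raise ValidationError(f"{path}: no data rows")
    return panels


def write_panels_csv(panels, path) -> None:
    """Inverse of :func:`read_panels_csv` (values at input precision)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_HEADER)
        for p in panels:
            writer.writerow([
                p.draw_date.isoformat(), p.sex.value, f"{p.a1c:g}",
                p.a1c_units.value, f"{p.fructosamine:g}", f"{p.ctni:g}",
                f"{p.ldl:g}",
            ])


_CONSTANT_KEYS = {f.name for f in dataclasses.fields(ReferenceConstants)}
_LIMIT_KEYS = {f.name for f in dataclasses.fields(ExclusionLimits)}


@dataclass(frozen=True)
class ToolConfig:
    """Effective tool configuration after applying overrides to defaults."""

    constants: ReferenceConstants = DEFAULT_CONSTANTS
    limits: ExclusionLimits = DEFAULT_LIMITS
    forecast_mode: str = "recompute"
    burden_mode: str = "index-linear"
    gap_threshold: float = GAP_THRESHOLD_DEFAULT
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.forecast_mode not in FORECAST_MODES:
            raise ConfigError(
                f"forecast_mode must be one of {FORECAST_MODES}, "
                f"got {self.forecast_mode!r}"
            )
        if self.burden_mode not in BURDEN_MODES:
            raise ConfigError(
                f"burden_mode must be one of {BURDEN_MODES}, "
                f"got {self.burden_mode!r}"
            )
        if not self.gap_threshold > 0:
            raise ConfigError(
                f"gap_threshold must be positive, got {self.gap_threshold!r}"
            )

    def echo(self) -> None:
        """Log the full effective constant set (auditable defaults)."""
        logger.info("effective constants: %s", self.constants)
        logger.info("effective exclusion limits: %s", self.limits)
        logger.info(
            "forecast_mode=%s burden_mode=%s gap_threshold=%g overrides=%s",
            self.forecast_mode, self.burden_mode, self.gap_threshold,
            self.overrides or "{}",
        )


def load_config(path=None) -> ToolConfig:
    """Build a :class:`ToolConfig` from a flat key/value file (or defaults).

    Recognised keys: every :class:`ReferenceConstants` and
    :class:`ExclusionLimits` field name, plus ``forecast_mode``,
    ``burden_mode`` and ``gap_threshold``.  Unknown keys are a configuration
    error, not a warning.
    """
    if path is None:
        return ToolConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat key/value mapping")
    const_over, limit_over, top = {}, {}, {}
    for key, value in raw.items():
        if key in _CONSTANT_KEYS:
            const_over[key] = float(value)
        elif key in _LIMIT_KEYS:
            limit_over[key] = float(value)
        elif key in ("forecast_mode", "burden_mode"):
            top[key] = str(value)
        elif key == "gap_threshold":
            top[key] = float(value)
        else:
            raise ConfigError(f"{path}: unknown configuration key {key!r}")
    if const_over:
        logger.info("overriding reference constants: %s", const_over)
    if limit_over:
        logger.info("overriding exclusion limits: %s", limit_over)
    return ToolConfig(
        constants=DEFAULT_CONSTANTS.replace(**const_over),
        limits=DEFAULT_LIMITS.replace(**limit_over),
        overrides=dict(raw),
        **top,
    )
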