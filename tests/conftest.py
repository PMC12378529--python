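import datetime as dt

import pytest

from glycotrack import BiomarkerPanel

# The representative annual report inputs: one simulated individual drifting
# from normoglycemia into prediabetes over four annual draws.
REPORT_ROWS = [
    ("2022-06-01", 5.5, 230, 2.6, 110),
    ("2023-06-01", 5.5, 230, 3.0, 120),
    ("2024-06-01", 5.7, 240, 3.2, 125),
    ("2025-06-01", 6.0, 262, 3.4, 130),
]


def make_panel(date, a1c_percent, fructosamine, ctni, ldl, sex="male"):
    return BiomarkerPanel(
        draw_date=date,
        sex=sex,
        a1c=a1c_percent,
        a1c_units="percent",
        fructosamine=fructosamine,
        ctni=ctni,
        ldl=ldl,
    )


@pytest.fixture
def report_panels():
    return [make_panel(*row) for row in REPORT_ROWS]


@pytest.fixture
def worked_example_panel():
    # A1c 39 mmol/mol (5.7%), fructosamine 240 µmol/L, with the cTnI/LDL
    # values of the 2024 report row.
    return make_panel("2024-06-01", 5.7, 240, 3.2, 125)


@pytest.fixture
def optimum_panel():
    # Panel sitting exactly at the optimal references / detection floors.
    return BiomarkerPanel(
        draw_date=dt.date(2024, 1, 1),
        sex="female",
        a1c=31,
        a1c_units="mmol/mol",
        fructosamine=200,
        ctni=1.6,
        ldl=60,
    )


@pytest.fixture
def report_csv(tmp_path):
    path = tmp_path / "panels.csv"
    lines = ["date,sex,a1c,a1c_units,fructosamine,ctni,ldl"]
    for date, a1c, fruct, ctni, ldl in REPORT_ROWS:
        lines.append(f"{date},male,{a1c},percent,{fruct},{ctni},{ldl}")
    path.write_text("\n".join(lines) + "\n")
    return path
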