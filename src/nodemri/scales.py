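"""Reporting-scale conversions for the nine node parameters.

Internally everything is computed in base physical units: diffusivities in
mm^2/s, MK and PF and V_e as unitless fractions, K^trans and K_ep in /min.
Clinical tables print the same quantities on fixed power-of-ten scales
(e.g. ADC 1232.62 means 1232.62e-6 mm^2/s, PF 236.09 means a perfusion
fraction of 0.236).  All CSV output and all table-shaped reports use the
reporting scale; all model code uses base units.  The round trip
``from_report(to_report(x)) == x`` is exact because the factors are exact
floats (powers of ten).
"""

from __future__ import annotations

PARAM_NAMES = (
    "adc",
    "md",
    "mk",
    "d_slow",
    "d_fast",
    "pf",
    "ktrans",
    "kep",
    "ve",
)

#: multiplicative factor taking an internal (base-unit) value to the
#: reporting scale used in the result tables.
REPORT_SCALE = {
    "adc": 1e6,  # mm^2/s -> 1e-6 mm^2/s units
    "md": 1e6,
    "d_slow": 1e6,
    "d_fast": 1e4,  # mm^2/s -> 1e-4 mm^2/s units
    "mk": 1e3,  # unitless -> 1e-3 units
    "pf": 1e3,  # fraction -> 1e-3 units
    "ktrans": 1e3,  # /min -> 1e-3/min units
    "kep": 1e3,
    "ve": 1e3,  # fraction -> 1e-3 units
}

REPORT_UNIT = {
    "adc": "1e-6 mm^2/s",
    "md": "1e-6 mm^2/s",
    "d_slow": "1e-6 mm^2/s",
    "d_fast": "1e-4 mm^2/s",
    "mk": "1e-3",
    "pf": "1e-3",
    "ktrans": "1e-3/min",
    "kep": "1e-3/min",
    "ve": "1e-3",
}


def to_report(value: float, param: str) -> float:
    """Convert an internal base-unit value to the reporting scale."""
    return value * REPORT_SCALE[param]


def from_report(value: float, param: str) -> float:
    """Convert a reporting-scale value back to internal base units."""
    return value / REPORT_SCALE[param]
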