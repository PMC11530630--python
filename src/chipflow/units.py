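"""Unit handling for network input files.

All internal quantities are SI (m, s, Pa, m^3/s, Pa*s, m^2/s, m^3, mol/m^3).
Input files may give any physical value either as a plain number (interpreted
as SI) or as ``{"value": x, "unit": "um"}``; this module converts on load.
"""

from __future__ import annotations

from typing import Any

# factor tables per dimension; every entry converts *to* SI on multiply
_LENGTH = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}
_TIME = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "min": 60.0, "h": 3600.0}
_PRESSURE = {"Pa": 1.0, "kPa": 1e3, "mbar": 1e2, "bar": 1e5, "psi": 6894.757293168}
_FLOW = {
    "m3/s": 1.0,
    "mL/s": 1e-6,
    "uL/s": 1e-9,
    "nL/s": 1e-12,
    "mL/min": 1e-6 / 60.0,
    "uL/min": 1e-9 / 60.0,
    "uL/h": 1e-9 / 3600.0,
}
_VISCOSITY = {"Pa.s": 1.0, "Pa*s": 1.0, "mPa.s": 1e-3, "mPa*s": 1e-3, "cP": 1e-3}
_DIFFUSIVITY = {"m2/s": 1.0, "cm2/s": 1e-4, "mm2/s": 1e-6, "um2/s": 1e-12}
_VOLUME = {"m3": 1.0, "L": 1e-3, "mL": 1e-6, "uL": 1e-9, "nL": 1e-12, "pL": 1e-15}
_AREA = {"m2": 1.0, "cm2": 1e-4, "mm2": 1e-6, "um2": 1e-12}
_CONCENTRATION = {"mol/m3": 1.0, "mM": 1.0, "M": 1e3, "uM": 1e-3}
_DIMENSIONLESS = {"": 1.0, "1": 1.0}

DIMENSIONS: dict[str, dict[str, float]] = {
    "length": _LENGTH,
    "time": _TIME,
    "pressure": _PRESSURE,
    "flow_rate": _FLOW,
    "viscosity": _VISCOSITY,
    "diffusivity": _DIFFUSIVITY,
    "volume": _VOLUME,
    "area": _AREA,
    "concentration": _CONCENTRATION,
    "dimensionless": _DIMENSIONLESS,
}


class UnitError(ValueError):
    """Raised for unknown units or malformed quantity objects."""


def to_si(value: Any, dimension: str, where: str = "") -> float:
    """Convert a JSON quantity (number or ``{"value", "unit"}``) to SI.

    ``dimension`` selects the admissible unit table; ``where`` is a
    JSON-pointer-like location used in error messages.
    """
    table = DIMENSIONS[dimension]
    if isinstance(value, bool):
        raise UnitError(f"{where}: expected a number, got a boolean")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, dict):
        extra = set(value) - {"value", "unit"}
        if extra:
            raise UnitError(f"{where}: unknown keys {sorted(extra)} in quantity object")
        if "value" not in value or "unit" not in value:
            raise UnitError(f"{where}: quantity object needs 'value' and 'unit'")
        raw, unit = value["value"], value["unit"]
        if not isinstance(raw, (int, float)) or isinstance(raw, bool):
            raise UnitError(f"{where}/value: expected a number")
        if unit not in table:
            raise UnitError(
                f"{where}/unit: unknown {dimension} unit {unit!r} "
                f"(known: {sorted(table)})"
            )
        return float(raw) * table[unit]
    raise UnitError(f"{where}: expected number or {{value, unit}} object")
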