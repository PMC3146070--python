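"""Percent-input for ChIP-qPCR measurements.

The enrichment of a ChIP sample relative to its input is

    % input = 100 · b^(−ΔCp) · (df_chip / df_input) · (f_input / 100)

with ΔCp = Cp(ChIP) − Cp(input), amplification base ``b``, dilution
factors ``df``, and ``f_input`` the percentage of extract set aside as
input.  At ΔCp = 0 and equal dilutions the result is exactly the input
fraction, which fixes the interpretation of the trailing percentage
term as a multiplicative fraction.

Two conventions for the amplification base are exposed: ``"2x"``
(default) takes b = 2 · efficiency, the literal reading of the source
formula; ``"1plus"`` takes b = 1 + efficiency, the common qPCR
convention in which efficiency 1 means perfect doubling.  The two agree
at efficiency 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class QpcrMeasurement:
    cp_chip: float
    cp_input: float
    efficiency: float = 1.0
    df_chip: float = 1.0
    df_input: float = 1.0
    input_fraction_percent: float = 1.0

    def __post_init__(self) -> None:
        import math
        for name in ("cp_chip", "cp_input", "efficiency", "df_chip",
                     "df_input", "input_fraction_percent"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite")
        if self.efficiency <= 0:
            raise ValidationError("efficiency must be > 0")
        if self.df_chip < 1 or self.df_input < 1:
            raise ValidationError("dilution factors must be >= 1")
        if not 0 < self.input_fraction_percent <= 100:
            raise ValidationError("input fraction must be in (0, 100] percent")


def amplification_base(efficiency: float, convention: str = "2x") -> float:
    if convention == "2x":
        return 2.0 * efficiency
    if convention == "1plus":
        return 1.0 + efficiency
    raise ConfigurationError(f"unknown base convention {convention!r}")


def percent_input(m: QpcrMeasurement, convention: str = "2x") -> dict:
    """Percent input with the components itemized.

    Returns a dict with keys ``percent_input``, ``delta_cp``, ``base``,
    ``dilution_ratio`` and ``input_fraction``.
    """
    delta_cp = m.cp_chip - m.cp_input
    b = amplification_base(m.efficiency, convention)
    if b <= 0:
        raise ValidationError("amplification base must be positive")
    if b <= 1.0 and delta_cp != 0:
        warnings.warn(
            f"amplification base {b:.3f} <= 1 is implausible for qPCR; "
            "check the efficiency value", stacklevel=2)
    dilution_ratio = m.df_chip / m.df_input
    input_fraction = m.input_fraction_percent / 100.0
    value = 100.0 * b ** (-delta_cp) * dilution_ratio * input_fraction
    return {"percent_input": value, "delta_cp": delta_cp, "base": b,
            "dilution_ratio": dilution_ratio,
            "input_fraction": input_fraction}
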