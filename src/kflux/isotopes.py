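"""Stable-isotope constants and delta-notation conversions for potassium.

Potassium has two stable isotopes, ³⁹K (~93.3% natural abundance) and ⁴¹K
(~6.7%).  Isotope-ratio measurements are reported in delta notation,

    δ⁴¹K = (R_sample / R_standard) − 1,

with R = ⁴¹K/³⁹K and R_standard the natural-abundance ratio (~0.0722).
Throughout this package deltas are expressed in per mil (‰), i.e. the
definition above multiplied by 1000.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class IsotopeConstants:
    """Physical constants of the ⁴¹K/³⁹K system.

    Attributes
    ----------
    natural_ratio
        ⁴¹K/³⁹K abundance ratio of the reference standard (dimensionless).
    fraction_39
        Natural ³⁹K atom fraction (dimensionless).
    molar_mass_41
        Molar mass of ⁴¹K in mg/mmol; for monovalent K⁺ one mmol is one mEq.
    """

    natural_ratio: float = 0.0722
    fraction_39: float = 0.933
    molar_mass_41: float = 40.96

    def __post_init__(self) -> None:
        if self.natural_ratio <= 0:
            raise ValueError("natural_ratio must be positive")
        if not 0.0 < self.fraction_39 < 1.0:
            raise ValueError("fraction_39 must lie in (0, 1)")
        if self.molar_mass_41 <= 0:
            raise ValueError("molar_mass_41 must be positive")
        # the ratio and the atom fraction describe the same composition;
        # allow only the small slack between published reference values
        implied = (1.0 - self.fraction_39) / self.fraction_39
        if abs(self.natural_ratio - implied) >= 0.01:
            raise ValueError(
                f"natural_ratio {self.natural_ratio} inconsistent with "
                f"fraction_39 {self.fraction_39} (implies ratio {implied:.4f})"
            )

    @property
    def fraction_41(self) -> float:
        """Natural ⁴¹K atom fraction."""
        return 1.0 - self.fraction_39


DEFAULT_CONSTANTS = IsotopeConstants()


def delta_from_ratio(ratio: float, constants: IsotopeConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a ⁴¹K/³⁹K ratio to delta notation in ‰.

    δ = 1000 × (R/R_standard − 1).
    """
    import numpy as np

    r = np.asarray(ratio, dtype=float)
    if np.any(r <= 0):
        raise ValueError("isotope ratio must be positive")
    out = 1000.0 * (r / constants.natural_ratio - 1.0)
    return float(out) if out.ndim == 0 else out


def ratio_from_delta(delta_permil: float, constants: IsotopeConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a delta value in ‰ back to an absolute ⁴¹K/³⁹K ratio."""
    import numpy as np

    d = np.asarray(delta_permil, dtype=float)
    out = constants.natural_ratio * (1.0 + d / 1000.0)
    if np.any(out <= 0):
        raise ValueError("delta corresponds to a non-positive ratio")
    return float(out) if out.ndim == 0 else out
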