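"""Acid-base speciation of the superoxide/hydroperoxyl pair.

The superoxide anion protonates to the hydroperoxyl radical,
O2·- + H+ = HO2·, with pKa 4.7, so by Henderson-Hasselbalch only a small
fraction is in the neutral HO2· form at physiological pH (~0.2% at
pH 7.4); the anionic form dominates and carries the membrane-charge
interaction studied elsewhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SpeciationParams", "protonated_fraction"]


@dataclass(frozen=True)
class SpeciationParams:
    pH: float
    pKa: float = 4.7

    def __post_init__(self) -> None:
        if not 0.0 < self.pH < 14.0:
            raise ValueError("pH must lie in (0, 14)")
        if not (self.pKa == self.pKa and abs(self.pKa) < 1e6):
            raise ValueError("pKa must be finite")


def protonated_fraction(params: SpeciationParams) -> float:
    """Fraction of the pair in the protonated (HO2·) form, in [0, 1].

    Henderson-Hasselbalch: f = 1 / (1 + 10^(pH - pKa)).
    """
    return 1.0 / (1.0 + 10.0 ** (params.pH - params.pKa))
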