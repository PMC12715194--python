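"""Hydration-shell energetics.

Back-of-the-envelope conversion of a change in the number of first-shell
water molecules at a residue into an enthalpy-scale energy range,
assuming each water gained or lost forms/breaks a fixed number of
hydrogen bonds whose strength lies in a bracket (default 1.5-9.5
kcal/mol per bond).  For a homotetrameric channel the per-subunit range
is multiplied by the number of equivalent copies.  The resulting bracket
is compared against the magnitude of the gating enthalpy to ask whether
hydration changes alone could account for it.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class HBondAssumptions:
    """Hydrogen-bond bracket used for the conversion."""

    e_min: float = 1.5   # kcal/mol per bond
    e_max: float = 9.5   # kcal/mol per bond
    bonds_per_water: float = 1.0

    def __post_init__(self):
        if not (0 < self.e_min <= self.e_max):
            raise ValueError("need 0 < e_min <= e_max")
        if self.bonds_per_water <= 0:
            raise ValueError("bonds_per_water must be positive")


@dataclass(frozen=True)
class EnergyRange:
    """An inclusive [low, high] energy bracket in kcal/mol."""

    low: float
    high: float

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError("low must not exceed high")


def energy_range(delta_waters: float,
                 assumptions: HBondAssumptions = HBondAssumptions()) -> EnergyRange:
    """Energy bracket for a change of ``delta_waters`` contacting waters.

    Fractional counts (MD-trajectory averages) are accepted; negative
    counts are invalid (pass the magnitude of the change).
    """
    if delta_waters < 0:
        raise ValueError("delta_waters must be >= 0 (pass the magnitude)")
    scale = delta_waters * assumptions.bonds_per_water
    return EnergyRange(low=scale * assumptions.e_min, high=scale * assumptions.e_max)


def tetramer_energy_range(per_subunit: EnergyRange, n_subunits: int = 4) -> EnergyRange:
    """Scale a per-subunit bracket to ``n_subunits`` equivalent copies."""
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    return EnergyRange(low=per_subunit.low * n_subunits,
                       high=per_subunit.high * n_subunits)


def sufficiency_check(rng: EnergyRange, dH_target: float) -> bool:
    """Can the bracket cover a gating enthalpy of magnitude ``dH_target``?

    The comparison is on magnitudes (gating enthalpies of cold-activated
    channels are negative) and uses >= at the boundary.
    """
    if dH_target <= 0:
        raise ValueError("dH_target is a magnitude and must be positive")
    return rng.high >= dH_target
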