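"""Minimal aqueous-speciation engine: ionic strength, Davies activity
coefficients, a carbonate subsystem, and saturation indices for a small set
of simple congruent minerals.

The saturation index of a mineral is SI = log10(IAP) - log10(K): positive
means supersaturated (precipitation-prone), negative undersaturated
(dissolution-prone).  Activities are molality * gamma with gamma from the
Davies equation

    log10 gamma = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I),   A = 0.5092 (25 C)

valid to roughly I = 0.5-0.7 mol/kg.  Carbonate ion activity is derived
from pH and bicarbonate via the second dissociation constant
(log K2 = -10.33); hydroxide from the water ion product.  Temperature is
fixed at 25 C (no van 't Hoff correction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

from . import datatables as dt
from .core import WaterSample

log = logging.getLogger("aquarisk")


class SpeciationError(KeyError):
    """A species required by a mineral reaction is not in the solution state."""


@dataclass(frozen=True)
class MineralPhase:
    """A dissolution reaction: signed stoichiometry over species and log K."""

    name: str
    stoich: Mapping[str, float]
    logk: float


#: bundled mineral set (overridable); names are lowercase
MINERALS: dict[str, MineralPhase] = {
    name: MineralPhase(name, spec["stoich"], spec["logk"])
    for name, spec in dt.MINERALS.items()
}

#: charge of each species symbol used in mineral reactions
_SPECIES_CHARGE = {
    "Na+1": 1, "K+1": 1, "Ca+2": 2, "Mg+2": 2, "Mn+2": 2, "Ni+2": 2,
    "Cl-1": -1, "HCO3-1": -1, "NO3-1": -1, "SO4-2": -2, "CO3-2": -2,
    "PO4-3": -3, "H+1": 1, "OH-1": -1,
}

_ION_TO_SPECIES = {
    "Na": "Na+1", "K": "K+1", "Ca": "Ca+2", "Mg": "Mg+2",
    "HCO3": "HCO3-1", "Cl": "Cl-1", "SO4": "SO4-2", "NO3": "NO3-1",
    "PO4": "PO4-3", "Mn": "Mn+2", "Ni": "Ni+2",
}


def ionic_strength(molalities: Mapping[str, float]) -> float:
    """I = 0.5 sum m_i z_i^2 over charged species (mol/kg)."""
    total = 0.0
    for species, m in molalities.items():
        if m < 0:
            raise ValueError(f"negative molality for {species}")
        z = _SPECIES_CHARGE.get(species, 0)
        total += m * z * z
    return 0.5 * total


def activity_coeff(z: int, I: float, A: float = dt.DAVIES_A) -> float:
    """Davies-equation activity coefficient for an ion of charge z."""
    if I < 0:
        raise ValueError("ionic strength must be nonnegative")
    if I > 0.7:
        log.warning("ionic strength %.3f beyond Davies validity (~0.7)", I)
    if z == 0 or I == 0.0:
        return 1.0
    sqrt_i = math.sqrt(I)
    log_gamma = -A * z * z * (sqrt_i / (1.0 + sqrt_i) - 0.3 * I)
    return 10.0 ** log_gamma


@dataclass
class SolutionState:
    """Molalities, ionic strength, and activities of one water sample."""

    molalities: dict[str, float]
    ph: float
    temp_C: float = 25.0
    ionic_strength_value: float = field(init=False)
    activities: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        I = ionic_strength(self.molalities)
        self.ionic_strength_value = I
        act = {}
        for species, m in self.molalities.items():
            z = _SPECIES_CHARGE.get(species, 0)
            act[species] = m * activity_coeff(z, I)
        a_h = 10.0 ** (-self.ph)
        act["H+1"] = a_h
        act.setdefault("OH-1", 10.0 ** dt.LOG_KW / a_h)
        if "HCO3-1" in act and "CO3-2" not in act:
            act["CO3-2"] = 10.0 ** dt.LOG_K2_CARBONATE * act["HCO3-1"] / a_h
        self.activities = act

    @classmethod
    def from_sample(cls, sample: WaterSample) -> "SolutionState":
        """Build a solution state from mg/L concentrations (density ~ 1 kg/L)."""
        mol = {}
        for ion, species in _ION_TO_SPECIES.items():
            if ion in sample.conc:
                mol[species] = sample.conc[ion] / 1000.0 / dt.ION_SPECS[ion][0]
        if math.isnan(sample.ph):
            raise SpeciationError("pH required for speciation")
        return cls(molalities=mol, ph=sample.ph,
                   temp_C=sample.temp_C if not math.isnan(sample.temp_C) else 25.0)


def saturation_index(
    solution: SolutionState | Mapping[str, float], mineral: MineralPhase | str
) -> float:
    """SI = log10(IAP) - log10(K) for one mineral in one solution.

    ``solution`` is a SolutionState or a bare species -> activity mapping.
    """
    if isinstance(mineral, str):
        try:
            mineral = MINERALS[mineral.lower()]
        except KeyError:
            raise SpeciationError(f"unknown mineral {mineral!r}") from None
    activities = (
        solution.activities if isinstance(solution, SolutionState) else solution
    )
    log_iap = 0.0
    for species, nu in mineral.stoich.items():
        a = activities.get(species)
        if a is None or a <= 0:
            raise SpeciationError(
                f"species {species} missing or zero for mineral {mineral.name}"
            )
        log_iap += nu * math.log10(a)
    return log_iap - mineral.logk


def classify_si(si: float, threshold: float = 0.0) -> str:
    """'supersaturated' / 'undersaturated' / 'equilibrium' about ``threshold``.

    The conventional threshold is SI = 0; a nonzero threshold is accepted
    for comparison with classification schemes that use one.
    """
    if si > threshold:
        return "supersaturated"
    if si < threshold:
        return "undersaturated"
    return "equilibrium"


def saturation_table(samples: list[WaterSample], minerals=None):
    """Per-sample SI for each requested mineral (DataFrame samples x minerals)."""
    import pandas as pd

    minerals = minerals if minerals is not None else list(MINERALS)
    rows = []
    for s in samples:
        state = SolutionState.from_sample(s)
        row = {"sample_id": s.sample_id, "group": s.group,
               "ionic_strength": state.ionic_strength_value}
        for m in minerals:
            try:
                row[m] = saturation_index(state, m)
            except SpeciationError:
                row[m] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
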