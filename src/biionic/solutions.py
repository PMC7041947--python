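"""Ionic species, recording solutions and Nernst-potential primitives.

Solutions are plain concentration maps (mM per species). The catalogue in
:data:`SOLUTION_CATALOGUE` reproduces every recipe used in the whole-cell
experiments this package models: the high-Na pipette, the divalent and
monovalent bath solutions, the NMDG-background Ca series, the NavPp mixed
baths, the Ca-block baths and the CHO mole-fraction series. Anions and
buffers (F, Cl, HEPES, EGTA, glucose) are recorded for provenance but are
impermeant; so is NMDG, a bulky organic cation used to replace permeant ions.

Activities are identified with concentrations throughout: the zero-current
permeability formulas the package implements are written directly in
concentrations, and no Debye-Hueckel correction is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "IonSpecies",
    "Solution",
    "ION_REGISTRY",
    "SOLUTION_CATALOGUE",
    "builtin_solutions",
    "get_solution",
    "nernst_potential",
    "nernst_slope_per_decade",
]


@dataclass(frozen=True)
class IonSpecies:
    """An ion species with its signed valence.

    Only cations with valence +1 or +2 can carry flux in the permeation
    model; everything else (anions, buffers, NMDG) is impermeant and is
    carried in solution records purely for provenance.
    """

    name: str
    valence: int
    permeant: bool = True

    def __post_init__(self) -> None:
        if self.permeant and self.valence not in (1, 2):
            raise ValueError(
                f"permeant species {self.name!r} must have valence +1 or +2, "
                f"got {self.valence}"
            )


#: Known species. NMDG is a cation but flagged impermeant; Mg2+ is permeant
#: in principle but no channel preset assigns it a permeability.
ION_REGISTRY: dict[str, IonSpecies] = {
    s.name: s
    for s in [
        IonSpecies("Na", 1),
        IonSpecies("K", 1),
        IonSpecies("Cs", 1),
        IonSpecies("Li", 1),
        IonSpecies("Ca", 2),
        IonSpecies("Sr", 2),
        IonSpecies("Ba", 2),
        IonSpecies("Mg", 2),
        IonSpecies("NMDG", 1, permeant=False),
        IonSpecies("Cl", -1, permeant=False),
        IonSpecies("F", -1, permeant=False),
        IonSpecies("HEPES", 0, permeant=False),
        IonSpecies("EGTA", 0, permeant=False),
        IonSpecies("glucose", 0, permeant=False),
        IonSpecies("ATP", 0, permeant=False),
    ]
}


class CatalogueError(KeyError):
    """Unknown solution label."""


@dataclass(frozen=True)
class Solution:
    """A named ionic solution: concentration map in mM plus its role.

    Lookups of absent ions return 0 mM. All concentrations must be >= 0.
    """

    label: str
    concentrations: Mapping[str, float] = field(default_factory=dict)
    role: str = "bath"  # "pipette" | "bath"

    def __post_init__(self) -> None:
        if self.role not in ("pipette", "bath"):
            raise ValueError(f"role must be 'pipette' or 'bath', got {self.role!r}")
        for ion, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {ion}: {c} mM")
        object.__setattr__(self, "concentrations", dict(self.concentrations))

    def __getitem__(self, ion: str) -> float:
        return self.concentrations.get(ion, 0.0)

    def get(self, ion: str) -> float:
        return self.concentrations.get(ion, 0.0)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "role": self.role,
            "concentrations_mM": dict(self.concentrations),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Solution":
        return cls(
            label=d["label"],
            concentrations=d["concentrations_mM"],
            role=d.get("role", "bath"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "Solution":
        return cls.from_dict(json.loads(s))


def _pip(label: str, **conc: float) -> Solution:
    return Solution(label, conc, role="pipette")


def _bath(label: str, **conc: float) -> Solution:
    return Solution(label, conc, role="bath")


# Printed recipes. Cation totals are what matter for permeation; the full
# recipe (salts split into ions) is kept so per-ion totals can be audited,
# e.g. high-Na pipette: 115 NaF + 35 NaCl -> Na 150, F 115, Cl 35.
SOLUTION_CATALOGUE: dict[str, Solution] = {
    s.label: s
    for s in [
        # pipette solutions (insect-cell recordings)
        _pip("high-na-pipette", Na=150, F=115, Cl=35, EGTA=10, HEPES=10),
        _pip("high-k-pipette", K=150, F=115, Cl=35, EGTA=10, HEPES=10),
        _pip("high-cs-pipette", Cs=150, F=115, Cl=35, EGTA=10, HEPES=10),
        _pip("low-na-pipette", Cs=140, Na=10, F=140, Cl=10, EGTA=10, HEPES=10),
        _pip("iv-pipette", Na=75, Cs=75, F=115, Cl=35, EGTA=10, HEPES=10),
        # bath solutions for selectivity measurements
        _bath("ca100-bath", Ca=100, Cl=200, HEPES=10, glucose=10),
        _bath("sr100-bath", Sr=100, Cl=200, HEPES=10, glucose=10),
        _bath("k-bath", K=150, Ca=2, Cl=154, HEPES=10, glucose=10),
        _bath("cs-bath", Cs=150, Ca=2, Cl=154, HEPES=10, glucose=10),
        # NMDG-background Ca series (bi-ionic E_rev vs [Ca]out)
        _bath("ca4-nmdg-bath", NMDG=144, Ca=4, Cl=152, HEPES=10),
        _bath("ca10-nmdg-bath", NMDG=135, Ca=10, Cl=155, HEPES=10),
        _bath("ca20-nmdg-bath", NMDG=120, Ca=20, Cl=160, HEPES=10),
        # NavPp mixed baths
        _bath("navpp-mixed-bath", NMDG=50, Na=40, Ca=40, Cl=170, HEPES=10),
        _bath("navpp-sr-mixed-bath", NMDG=50, Na=40, Sr=40, Cl=170, HEPES=10),
        _bath("navpp-cs-bath", NMDG=110, Na=40, Ca=3, Cl=156, HEPES=10),
        # Ca-block baths
        _bath("ca-block-1.5", Na=30, NMDG=120, Ca=1.5, Cl=153, HEPES=10, glucose=10),
        _bath("ca-block-10", Na=30, NMDG=105, Ca=10, Cl=155, HEPES=10, glucose=10),
        # CHO-cell mole-fraction series (NaCl/CaCl2 ratios)
        _bath("mole-fraction-135:0", Na=135, Ca=0, Cl=135),
        _bath("mole-fraction-108:18", Na=108, Ca=18, Cl=144),
        _bath("mole-fraction-81:36", Na=81, Ca=36, Cl=153),
        _bath("mole-fraction-54:54", Na=54, Ca=54, Cl=162),
        _bath("mole-fraction-27:82", Na=27, Ca=82, Cl=191),
        _bath("mole-fraction-0:90", Na=0, Ca=90, Cl=180),
        # the near-zero-Ca point of the anomalous-mole-fraction check
        _bath("mole-fraction-133.7:0.9", Na=133.7, Ca=0.9, Cl=135.5),
        _bath("ca-free-bath", Na=135, Cl=135, EGTA=1),
        # CHO recording solutions
        _pip("cho-pipette", K=130, Na=10, Ca=0.1, Mg=4, Cl=138.2, EGTA=3,
             HEPES=10, ATP=5),
        _bath("cho-bath", Na=135, K=4, Ca=1, Mg=5, Cl=151, HEPES=10),
    ]
}


def builtin_solutions() -> dict[str, Solution]:
    """Return a copy of the built-in solution catalogue."""
    return dict(SOLUTION_CATALOGUE)


def get_solution(label: str) -> Solution:
    """Look up a catalogued solution by label.

    Raises
    ------
    CatalogueError
        If the label is unknown; the message lists available labels.
    """
    try:
        return SOLUTION_CATALOGUE[label]
    except KeyError:
        available = ", ".join(sorted(SOLUTION_CATALOGUE))
        raise CatalogueError(
            f"unknown solution {label!r}; available: {available}"
        ) from None


def catalogue_table() -> "object":
    """The catalogue as a tidy pandas DataFrame (one row per solution/ion)."""
    import pandas as pd

    rows = []
    for sol in SOLUTION_CATALOGUE.values():
        for ion, c in sol.concentrations.items():
            rows.append(
                {"label": sol.label, "role": sol.role, "ion": ion, "mM": c}
            )
    return pd.DataFrame(rows)


def nernst_potential(
    ion: IonSpecies | str,
    c_out: float,
    c_in: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Equilibrium (Nernst) potential of one ion in mV.

    E = (RT / zF) ln(c_out / c_in), antisymmetric under swapping the two
    concentrations. Both concentrations must be strictly positive.
    """
    if isinstance(ion, str):
        ion = ION_REGISTRY[ion]
    if ion.valence == 0:
        raise ValueError(f"{ion.name} has zero valence; no Nernst potential")
    if c_out <= 0 or c_in <= 0:
        raise ValueError(
            f"Nernst potential of {ion.name} requires positive concentrations "
            f"(got c_out={c_out}, c_in={c_in} mM)"
        )
    return constants.rt_over_f_mV / ion.valence * math.log(c_out / c_in)


def nernst_slope_per_decade(
    valence: int, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Theoretical Nernst slope RT ln(10) / zF in mV per tenfold
    concentration change (~59.2 mV for z=+1, ~29.6 mV for z=+2 at 298.1 K)."""
    if valence == 0:
        raise ValueError("Nernst slope undefined for zero valence")
    return constants.rt_over_f_mV * math.log(10.0) / valence


def total_cation(solution: Solution, ions: Iterable[str]) -> float:
    """Summed concentration of the named ions in a solution (mM)."""
    return sum(solution.get(i) for i in ions)
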