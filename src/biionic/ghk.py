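"""Goldman-Hodgkin-Katz flux model and permeability-ratio inversion.

The forward model sums independent constant-field fluxes over the permeant
cations (valence +1 or +2):

    I(V) = sum_X  P_X * z_X^2 * psi * ([X]_in - [X]_out e^{-z_X psi})
                                      / (1 - e^{-z_X psi}),
    psi = V F / RT,

in arbitrary current units (outward positive, V = inside minus outside).
I(V) is strictly increasing in V, so the zero-current (reversal) potential
is unique and can be bracketed on [-200, +200] mV.

The inverse direction implements the two printed zero-current expressions
used to turn a measured bi-ionic reversal potential into permeability
ratios: the two-ion Na/Ca form (also used for Sr) and the extended
three-ion form for a monovalent test cation M in the presence of Ca.
Both are re-derived from the zero-current condition of the forward model,
which is what makes solve-then-substitute round trips exact; the grouping
of the three-ion form is documented in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .solutions import ION_REGISTRY, Solution

__all__ = [
    "PermeabilitySet",
    "ReversalSolveReport",
    "ghk_current",
    "reversal_potential",
    "pca_pna_from_erev",
    "pm_pna_from_erev",
]

#: Below this |z psi| the per-ion flux factor switches to its Taylor series
#: (the V=0 singularity is removable; the series avoids cancellation).
_SERIES_THRESHOLD = 1e-4


class ModelError(ValueError):
    """Ill-posed permeation model (e.g. no permeant ion anywhere)."""


class NoReversalError(RuntimeError):
    """No zero crossing of the GHK current on the search bracket."""


class DegenerateConditionError(ZeroDivisionError):
    """A denominator of a printed permeability expression vanishes."""


@dataclass(frozen=True)
class PermeabilitySet:
    """Relative permeabilities P_X / P_Na with an absolute scale.

    The Na entry always exists and equals 1; ratios are dimensionless and
    nonnegative. ``scale`` is the absolute P_Na in arbitrary flux units.
    """

    ratios: Mapping[str, float] = field(default_factory=dict)
    scale: float = 1.0

    def __post_init__(self) -> None:
        r = dict(self.ratios)
        r.setdefault("Na", 1.0)
        if not math.isclose(r["Na"], 1.0, rel_tol=0, abs_tol=0):
            raise ValueError(f"P_Na must be 1 by definition, got {r['Na']}")
        for ion, v in r.items():
            if v < 0:
                raise ValueError(f"negative permeability ratio for {ion}: {v}")
            species = ION_REGISTRY.get(ion)
            if species is None:
                raise ValueError(f"unknown ion species {ion!r}")
            if not species.permeant:
                raise ValueError(f"{ion} is impermeant; cannot assign permeability")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "ratios", r)

    def __getitem__(self, ion: str) -> float:
        return self.ratios.get(ion, 0.0)

    def items(self):
        return self.ratios.items()


@dataclass(frozen=True)
class ReversalSolveReport:
    """Result of the bracketed zero-current solve."""

    E_rev: float  # mV
    bracket: tuple[float, float]
    iterations: int
    residual: float  # current units at E_rev

    def __float__(self) -> float:
        return self.E_rev


def _flux_factor(psi, c_in: float, c_out: float, z: int):
    """Per-ion factor psi (c_in - c_out e^{-z psi}) / (1 - e^{-z psi}).

    Vectorized in psi. Near psi = 0 uses the second-order series
    (dC + a (c_in+c_out)/2 + a^2 dC / 12) / z with a = z psi.
    """
    psi = np.asarray(psi, dtype=float)
    a = z * psi
    small = np.abs(a) < _SERIES_THRESHOLD
    dC = c_in - c_out
    series = (dC + a * (c_in + c_out) / 2.0 + a * a * dC / 12.0) / z
    with np.errstate(over="ignore", invalid="ignore"):
        safe_a = np.where(small, 1.0, a)
        direct = psi * (c_in - c_out * np.exp(-safe_a)) / (-np.expm1(-safe_a))
    out = np.where(small, series, direct)
    return out if out.ndim else float(out)


def ghk_current(
    V,
    perms: PermeabilitySet,
    pipette: Solution,
    bath: Solution,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Total GHK current density at membrane potential V (mV).

    Outward positive; arbitrary units set by ``perms.scale``. Vectorized
    in V. Raises :class:`ModelError` if no permeant ion with nonzero
    permeability is present on either side.
    """
    psi = np.asarray(V, dtype=float) * constants.f_over_rt_per_mV
    total = np.zeros_like(psi)
    any_flux = False
    for ion, ratio in perms.items():
        if ratio == 0.0:
            continue
        z = ION_REGISTRY[ion].valence
        c_in = pipette.get(ion)
        c_out = bath.get(ion)
        if c_in == 0.0 and c_out == 0.0:
            continue
        any_flux = True
        total = total + ratio * z * z * _flux_factor(psi, c_in, c_out, z)
    if not any_flux:
        raise ModelError(
            "no permeant ion with nonzero permeability present on either side"
        )
    total = perms.scale * total
    return total if total.ndim else float(total)


def reversal_potential(
    perms: PermeabilitySet,
    pipette: Solution,
    bath: Solution,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    bracket: tuple[float, float] = (-200.0, 200.0),
    xtol: float = 1e-12,
) -> ReversalSolveReport:
    """Solve I(E_rev) = 0 on the bracket by Brent's method.

    The GHK current is strictly increasing in V, so the root is unique
    when a sign change exists. Raises :class:`NoReversalError` (with the
    end-point currents in the message) otherwise.
    """
    lo, hi = bracket

    def f(v: float) -> float:
        return ghk_current(v, perms, pipette, bath, constants)

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return ReversalSolveReport(lo, bracket, 0, 0.0)
    if f_hi == 0.0:
        return ReversalSolveReport(hi, bracket, 0, 0.0)
    if f_lo * f_hi > 0:
        raise NoReversalError(
            f"no reversal in range [{lo}, {hi}] mV: "
            f"I({lo}) = {f_lo:.6g}, I({hi}) = {f_hi:.6g}"
        )
    root, res = brentq(f, lo, hi, xtol=xtol, full_output=True)
    return ReversalSolveReport(
        E_rev=float(root),
        bracket=bracket,
        iterations=res.iterations,
        residual=float(f(root)),
    )


def _exps(e_rev_mV: float, constants: PhysicalConstants):
    x = e_rev_mV * constants.f_over_rt_per_mV
    return math.exp(-x), math.exp(-2.0 * x)


def pca_pna_from_erev(
    e_rev_mV: float,
    na_in: float,
    na_out: float,
    ca_in: float,
    ca_out: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Two-ion (Na/divalent) permeability ratio from a reversal potential.

    Implements

        P_Ca/P_Na = -([Na]in - [Na]out e^{-uE}) (1 - e^{-2uE})
                    / [ 4 ([Ca]in - [Ca]out e^{-2uE}) (1 - e^{-uE}) ],
        u = F/RT,

    evaluated through the exact factorization
    (1 - e^{-2uE}) / (1 - e^{-uE}) = 1 + e^{-uE}, which is regular at
    E = 0 (there the factor equals its analytic limit 2). The same
    expression serves Sr2+ with Sr concentrations in place of Ca.
    """
    em1, em2 = _exps(e_rev_mV, constants)
    denom = 4.0 * (ca_in - ca_out * em2)
    if abs(denom) < 1e-300:
        raise DegenerateConditionError(
            "divalent flux term [Ca]in - [Ca]out e^(-2uE) vanishes at "
            f"E_rev = {e_rev_mV} mV"
        )
    return -(na_in - na_out * em1) * (1.0 + em1) / denom


def pm_pna_from_erev(
    e_rev_mV: float,
    pca_pna: float,
    na_in: float,
    na_out: float,
    ca_in: float,
    ca_out: float,
    m_in: float,
    m_out: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Three-ion permeability ratio P_M/P_Na for a monovalent test cation M.

    From the zero-current condition of a Na + M + Ca system,

        A_Na + (P_M/P_Na) A_M + 4 (P_Ca/P_Na) A_Ca / (1 + e^{-uE}) = 0,

    with A_Na = [Na]in - [Na]out e^{-uE}, A_M likewise for M, and
    A_Ca = [Ca]in - [Ca]out e^{-2uE}; hence

        P_M/P_Na = -(A_Na + 4 (P_Ca/P_Na) A_Ca / (1 + e^{-uE})) / A_M.

    This grouping is algebraically identical to the printed bracketed
    expression (see docs/methods.md for the derivation). With the Ca terms
    zero it reduces to the classic two-ion bi-ionic formula.
    """
    em1, em2 = _exps(e_rev_mV, constants)
    a_na = na_in - na_out * em1
    a_m = m_in - m_out * em1
    a_ca = ca_in - ca_out * em2
    if m_in == 0.0 and m_out == 0.0:
        raise ValueError("test cation M absent on both sides")
    if abs(a_m) < 1e-300:
        raise DegenerateConditionError(
            "monovalent flux term [M]in - [M]out e^(-uE) vanishes at "
            f"E_rev = {e_rev_mV} mV"
        )
    return -(a_na + 4.0 * pca_pna * a_ca / (1.0 + em1)) / a_m
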