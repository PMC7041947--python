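"""Inference chain from current traces to permeability tables.

trace -> P/N leak subtraction -> I-V curve / ramp reversal potential ->
GHK permeability ratio -> per-cell aggregation (mean +/- SEM, n), plus the
reversal-potential-vs-concentration slope regression and the mole-fraction
current summary used to check for an anomalous mole-fraction effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .ghk import pca_pna_from_erev, pm_pna_from_erev
from .simulate import CurrentTrace
from .solutions import Solution

__all__ = [
    "IVCurve",
    "PermeabilityResult",
    "SlopeFit",
    "CellRecord",
    "pn_subtract",
    "extract_erev_from_ramp",
    "build_iv_curve",
    "permeability_table",
    "erev_concentration_slope",
    "mole_fraction_summary",
]


class AlignmentError(ValueError):
    """Main and sub-sweeps do not share shape/sampling."""


class CrossingError(RuntimeError):
    """Zero or multiple zero crossings in the ramp window."""


class NormalizationError(ValueError):
    """Missing reference sweep for I-V normalization."""


@dataclass
class IVCurve:
    """Current-voltage relation, optionally normalized to a reference."""

    V: np.ndarray
    I: np.ndarray
    normalization: str | None = None

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.I = np.asarray(self.I, dtype=float)


@dataclass
class PermeabilityResult:
    """Per-cell permeability ratios aggregated as mean +/- SEM with n."""

    ratio_name: str
    per_cell_values: list[float]
    channel: str = ""
    footnote: str | None = None

    @property
    def n(self) -> int:
        return len(self.per_cell_values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_cell_values))

    @property
    def sem(self) -> float:
        # sd with n-1 denominator; a single cell reports SEM 0 (flagged by n=1)
        if self.n < 2:
            return 0.0
        return float(np.std(self.per_cell_values, ddof=1) / math.sqrt(self.n))


@dataclass(frozen=True)
class SlopeFit:
    """OLS of reversal potential on log10 concentration."""

    slope: float  # mV per decade
    intercept: float  # mV
    included_concentrations: tuple[float, ...]
    r_squared: float
    slope_se: float


@dataclass(frozen=True)
class CellRecord:
    """One cell's measured reversal potential under a named condition.

    ``ratio_name`` selects the inverse formula: 'P_Ca/P_Na' or 'P_Sr/P_Na'
    use the two-ion divalent expression; 'P_K/P_Na' / 'P_Cs/P_Na' use the
    extended three-ion expression and require ``pca_pna`` (that cell's or
    condition's Ca:Na ratio) to be supplied.
    """

    cell_id: str
    channel: str
    ratio_name: str
    e_rev_mV: float
    pipette: Solution
    bath: Solution
    pca_pna: float | None = None
    footnote: str | None = None


def pn_subtract(
    main: CurrentTrace, subs: Sequence[CurrentTrace], n_sub: int | None = None
) -> CurrentTrace:
    """Subtract the leak estimated from P/N sub-sweeps from the main sweep.

    The leak estimate at each sample is the holding-level leak plus the sum
    of the sub-sweeps' deviations from their own holding baselines (each
    sub-sweep carries 1/n_sub of the main excursion, so the summed
    deviations reconstruct the full-excursion leak). Shapes and sampling
    must match.
    """
    if not subs:
        raise AlignmentError("no sub-sweeps given")
    if n_sub is None:
        n_sub = len(subs)
    for sub in subs:
        if sub.current.shape != main.current.shape:
            raise AlignmentError("sub-sweep shape differs from main sweep")
        if sub.sample_rate_khz != main.sample_rate_khz:
            raise AlignmentError("sub-sweep sampling differs from main sweep")

    def holding_baseline(trace: CurrentTrace) -> float:
        seg0 = trace.metadata["segments"][0]
        return float(np.mean(trace.current[seg0["start"]:seg0["stop"]]))

    baselines = [holding_baseline(s) for s in subs]
    estimate = np.mean(baselines) + sum(
        s.current - b for s, b in zip(subs, baselines)
    )
    corrected = dc_replace(main, current=main.current - estimate)
    corrected.metadata = dict(main.metadata, leak_subtracted=True)
    return corrected


def extract_erev_from_ramp(
    trace: CurrentTrace,
    ramp_segment: int | None = None,
    smoothing: int | None = None,
) -> float:
    """Reversal potential from the zero crossing of a ramp sweep.

    Finds the (single) sign change of the current within the ramp segment
    after optional moving-average smoothing of the given odd width, and
    linearly interpolates the command voltage at the crossing.
    """
    segments = trace.metadata.get("segments", [])
    if ramp_segment is None:
        ramp_idx = next(
            (i for i, s in enumerate(segments) if s["kind"] == "ramp"), None
        )
        if ramp_idx is None:
            raise CrossingError("trace has no ramp segment")
    else:
        ramp_idx = ramp_segment
    seg = segments[ramp_idx]
    i0, i1 = seg["start"], seg["stop"]
    current = trace.current[i0:i1]
    voltage = trace.command_V[i0:i1]
    if smoothing is not None and smoothing > 1:
        kernel = np.ones(smoothing) / smoothing
        current = np.convolve(current, kernel, mode="valid")
        half = (smoothing - 1) // 2
        voltage = voltage[half: half + len(current)]
    signs = np.sign(current)
    nonzero = signs != 0
    change = np.flatnonzero(np.diff(signs[nonzero]) != 0)
    idx_map = np.flatnonzero(nonzero)
    if len(change) == 0:
        if np.any(signs == 0):
            return float(voltage[np.flatnonzero(signs == 0)[0]])
        raise CrossingError("no zero crossing in ramp window (0 crossings)")
    if len(change) > 1:
        raise CrossingError(
            f"multiple zero crossings in ramp window ({len(change)} crossings)"
        )
    j0 = idx_map[change[0]]
    j1 = idx_map[change[0] + 1]
    i_a, i_b = current[j0], current[j1]
    v_a, v_b = voltage[j0], voltage[j1]
    return float(v_a - i_a * (v_b - v_a) / (i_b - i_a))


def build_iv_curve(
    sweeps: Sequence[CurrentTrace],
    measure: str = "peak",
    test_segment: int = 1,
    normalization_ref: tuple[float, float] | None = None,
    inward_reference: bool = False,
) -> IVCurve:
    """Per-sweep current measurement versus test-step voltage.

    ``measure='peak'`` takes the signed extremum during the test segment,
    ``'steady'`` the mean of its final 10%. ``normalization_ref`` is
    (reference voltage, tolerance); the measurement at that step level
    divides all values, so the reference point maps to exactly 1 (or -1
    with ``inward_reference`` for an inward reference current).
    """
    if measure not in ("peak", "steady"):
        raise ValueError("measure must be 'peak' or 'steady'")
    vs, cs = [], []
    for trace in sweeps:
        seg = trace.metadata["segments"][test_segment]
        chunk = trace.current[seg["start"]:seg["stop"]]
        if measure == "peak":
            val = chunk[np.argmax(np.abs(chunk))]
        else:
            n = len(chunk)
            val = np.mean(chunk[-max(1, n // 10):])
        vs.append(float(seg["v_end"]))
        cs.append(float(val))
    vs_arr = np.array(vs)
    cs_arr = np.array(cs)
    norm_desc = None
    if normalization_ref is not None:
        ref_v, tol = normalization_ref
        hit = np.flatnonzero(np.abs(vs_arr - ref_v) <= tol)
        if len(hit) == 0:
            raise NormalizationError(f"no sweep at reference step {ref_v} mV")
        ref = cs_arr[hit[0]]
        if ref == 0:
            raise NormalizationError("reference measurement is zero")
        cs_arr = cs_arr / abs(ref) if inward_reference else cs_arr / ref
        norm_desc = f"{measure}@{ref_v}mV"
    return IVCurve(V=vs_arr, I=cs_arr, normalization=norm_desc)


def _ratio_for_record(
    rec: CellRecord, constants: PhysicalConstants
) -> float:
    divalent_of = {"P_Ca/P_Na": "Ca", "P_Sr/P_Na": "Sr"}
    monovalent_of = {"P_K/P_Na": "K", "P_Cs/P_Na": "Cs"}
    if rec.ratio_name in divalent_of:
        ion = divalent_of[rec.ratio_name]
        return pca_pna_from_erev(
            rec.e_rev_mV,
            rec.pipette.get("Na"), rec.bath.get("Na"),
            rec.pipette.get(ion), rec.bath.get(ion),
            constants,
        )
    if rec.ratio_name in monovalent_of:
        if rec.pca_pna is None:
            raise ValueError(
                f"record {rec.cell_id}: {rec.ratio_name} requires P_Ca/P_Na"
            )
        ion = monovalent_of[rec.ratio_name]
        return pm_pna_from_erev(
            rec.e_rev_mV, rec.pca_pna,
            rec.pipette.get("Na"), rec.bath.get("Na"),
            rec.pipette.get("Ca"), rec.bath.get("Ca"),
            rec.pipette.get(ion), rec.bath.get(ion),
            constants,
        )
    raise ValueError(f"unknown ratio {rec.ratio_name!r}")


def permeability_table(
    records: Sequence[CellRecord],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> list[PermeabilityResult]:
    """Per-cell ratios aggregated into one row per (channel, ratio)."""
    groups: dict[tuple[str, str], PermeabilityResult] = {}
    for rec in records:
        value = _ratio_for_record(rec, constants)
        key = (rec.channel, rec.ratio_name)
        if key not in groups:
            groups[key] = PermeabilityResult(
                ratio_name=rec.ratio_name,
                per_cell_values=[],
                channel=rec.channel,
                footnote=rec.footnote,
            )
        groups[key].per_cell_values.append(value)
    return list(groups.values())


def erev_concentration_slope(
    points: Sequence[tuple[float, float]],
    include: Sequence[float] | None = None,
) -> SlopeFit:
    """OLS slope of E_rev (mV) against log10([X]out in mM).

    ``include`` restricts the fit to the listed concentrations (e.g. the
    well-behaved {4, 10, 20} subset versus the full series).
    """
    pts = list(points)
    if include is not None:
        wanted = set(include)
        pts = [p for p in pts if p[0] in wanted]
    if len(pts) < 2:
        raise ValueError("need >= 2 concentrations to fit a slope")
    conc = np.array([p[0] for p in pts], dtype=float)
    erev = np.array([p[1] for p in pts], dtype=float)
    res = stats.linregress(np.log10(conc), erev)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        included_concentrations=tuple(sorted(set(conc))),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
    )


def mole_fraction_summary(
    trace_sets: Sequence[dict],
    measure_V: float = -20.0,
    test_segment: int = 1,
    tolerance: float | None = None,
) -> dict:
    """Normalized peak inward current versus Ca mole fraction.

    Each entry of ``trace_sets`` is a dict with ``f_ca`` and ``traces``
    (as produced by the mole-fraction series generator). The peak inward
    current during the test step at ``measure_V`` is taken per set and
    normalized to the maximum across sets. The verdict is True when no
    interior point dips below both neighbors by more than the tolerance
    (absence of an anomalous mole-fraction effect); the default tolerance
    is 2x the estimated noise sd of the normalized amplitudes.
    """
    if len(trace_sets) < 3:
        raise ValueError("need >= 3 mole fractions")
    rows = []
    for entry in trace_sets:
        candidates = []
        for trace in entry["traces"]:
            seg = trace.metadata["segments"][test_segment]
            if abs(seg["v_end"] - measure_V) > 1e-6:
                continue
            chunk = trace.current[seg["start"]:seg["stop"]]
            candidates.append(float(-np.min(chunk)))  # inward magnitude
        if not candidates:
            raise ValueError(
                f"no sweep at measure voltage {measure_V} mV in one trace set"
            )
        rows.append((float(entry["f_ca"]), max(candidates)))
    rows.sort()
    f_ca = np.array([r[0] for r in rows])
    amp = np.array([r[1] for r in rows])
    peak = np.max(np.abs(amp))
    if peak == 0:
        raise ValueError("all-zero amplitudes")
    norm = amp / peak
    if tolerance is None:
        # noise scale from second differences (zero for smooth monotone data)
        tolerance = 2.0 * float(np.std(np.diff(norm, 2))) / math.sqrt(6.0) \
            if len(norm) >= 3 else 0.0
    dips = [
        i
        for i in range(1, len(norm) - 1)
        if norm[i] < norm[i - 1] - tolerance and norm[i] < norm[i + 1] - tolerance
    ]
    return {
        "f_ca": f_ca,
        "normalized_amplitude": norm,
        "monotonic": len(dips) == 0,
        "dip_indices": dips,
        "tolerance": tolerance,
    }
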