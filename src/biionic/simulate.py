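"""Synthetic whole-cell voltage-clamp recordings.

Generates idealized (capacitance-free) current traces with the statistical
structure the analysis pipeline assumes:

    I(t) = G_scale * m(t) * h(t) * I_GHK(V(t)) + g_leak * V(t) + noise,

where the activation gate m relaxes mono-exponentially toward its
steady-state Boltzmann value (tau_act when opening, tau_deact when
closing), the optional inactivation gate h relaxes toward 0 above a
threshold potential with tau_inact (tau_inact = inf disables
inactivation), the ionic driving force is the GHK current for the given
solutions and permeability set, leak is ohmic through 0 mV, and noise is
white Gaussian with a seeded generator (identical seeds give identical
traces bit for bit).

Protocol builders cover the standard stimulus families: step series from a
holding potential, voltage ramps through the reversal potential, and
prepulse/tail protocols. A P/N leak-subtraction family generator produces
the scaled sub-sweeps of the P/10 protocol delivered at the holding
potential, and a mole-fraction series generator sweeps bath Na/Ca ratios
at a fixed channel and protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .gating import BoltzmannParams, boltzmann_activation
from .ghk import ModelError, PermeabilitySet, ghk_current
from .solutions import Solution

__all__ = [
    "Segment",
    "VoltageProtocol",
    "CurrentTrace",
    "SimChannelSpec",
    "CHANNEL_PRESETS",
    "step_protocol",
    "ramp_protocol",
    "tail_protocol",
    "simulate",
    "simulate_pn_leak_family",
    "generate_mole_fraction_series",
    "mole_fraction",
]


@dataclass(frozen=True)
class Segment:
    """One piece of a voltage command: hold/step (constant) or ramp."""

    kind: str  # "hold" | "step" | "ramp"
    v_start: float  # mV
    v_end: float  # mV
    duration_ms: float

    def __post_init__(self) -> None:
        if self.kind not in ("hold", "step", "ramp"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be positive")
        if self.kind == "ramp" and self.v_start == self.v_end:
            raise ValueError("ramp must have v_start != v_end")
        if self.kind != "ramp" and self.v_start != self.v_end:
            raise ValueError("constant segments must have v_start == v_end")


def const_segment(kind: str, v: float, duration_ms: float) -> Segment:
    return Segment(kind, v, v, duration_ms)


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise voltage command with optional per-sweep overrides.

    ``sweep_table`` maps, per sweep, segment index -> (v_start, v_end)
    replacing that segment's voltages. An empty table means one sweep.
    """

    segments: tuple[Segment, ...]
    holding_V: float = -140.0
    sample_rate_khz: float = 20.0
    sweep_table: tuple[Mapping[int, tuple[float, float]], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "sweep_table", tuple(self.sweep_table))
        if not self.segments:
            raise ValueError("protocol needs at least one segment")

    @property
    def n_sweeps(self) -> int:
        return max(1, len(self.sweep_table))

    def sweep_segments(self, sweep: int) -> list[Segment]:
        segs = list(self.segments)
        if self.sweep_table:
            for idx, (v0, v1) in self.sweep_table[sweep].items():
                s = segs[idx]
                segs[idx] = Segment(s.kind, v0, v1, s.duration_ms)
        return segs

    def command(self, sweep: int = 0) -> tuple[np.ndarray, np.ndarray, list[dict]]:
        """Sampled (time_ms, command_mV, segment index table) for one sweep."""
        dt = 1.0 / self.sample_rate_khz
        chunks = []
        seg_table = []
        start = 0
        for seg in self.sweep_segments(sweep):
            n = max(1, int(round(seg.duration_ms * self.sample_rate_khz)))
            if seg.kind == "ramp":
                # sample at the end of each dt interval
                frac = (np.arange(n) + 1) / n
                v = seg.v_start + (seg.v_end - seg.v_start) * frac
            else:
                v = np.full(n, seg.v_end)
            chunks.append(v)
            seg_table.append(
                {"kind": seg.kind, "v_start": seg.v_start, "v_end": seg.v_end,
                 "start": start, "stop": start + n}
            )
            start += n
        command = np.concatenate(chunks)
        time = np.arange(len(command)) * dt
        return time, command, seg_table


@dataclass
class CurrentTrace:
    """One sampled sweep: time grid, command voltage and current."""

    time: np.ndarray  # ms
    command_V: np.ndarray  # mV
    current: np.ndarray  # normalized units
    sample_rate_khz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.command_V = np.asarray(self.command_V, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if not (len(self.time) == len(self.command_V) == len(self.current)):
            raise ValueError("time, command_V and current must be equal length")


@dataclass(frozen=True)
class SimChannelSpec:
    """Channel preset: permeation, gating, kinetics, leak and noise.

    Time constants are illustrative — no kinetic values are available for
    these channels — and the analysis surfaces never depend on them.
    ``tau_inact = inf`` disables inactivation (used for the
    slowly-inactivating G240A/T232A-like presets). ``ca_block_ic50``
    optionally applies a phenomenological conductance factor
    1/(1 + [Ca]out/IC50), off by default.
    """

    label: str
    perms: PermeabilitySet
    gating: BoltzmannParams
    tau_act: float = 5.0  # ms
    tau_deact: float = 2.0  # ms
    tau_inact: float = math.inf  # ms
    inact_threshold: float = -40.0  # mV; h relaxes toward 0 above this
    G_scale: float = 1.0
    leak_conductance: float = 0.0  # current units per mV
    noise_sd: float = 0.0
    seed: int = 0
    ca_block_ic50: float | None = None

    def __post_init__(self) -> None:
        for name in ("tau_act", "tau_deact", "tau_inact"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _preset(label, ratios, v_half, tau_inact=math.inf, **kw) -> SimChannelSpec:
    return SimChannelSpec(
        label=label,
        perms=PermeabilitySet(ratios=ratios),
        gating=BoltzmannParams(V_half=v_half, k_slope=8.0),
        tau_inact=tau_inact,
        **kw,
    )


#: Channel presets. Permeability ratios are the measured Table-style
#: mean values; gating midpoints are the reported Boltzmann fits
#: (CavMr -51.7 mV, NavPp T232A -17.11 mV). For the highly Ca-selective
#: channels the monovalent ratios were reported vs Ca and are converted
#: to the vs-Na convention here (P_K/P_Na = (P_K/P_Ca) * (P_Ca/P_Na)).
CHANNEL_PRESETS: dict[str, SimChannelSpec] = {
    p.label: p
    for p in [
        _preset("cavmr-wt",
                {"Ca": 218.0, "Sr": 40.6, "K": 0.0036 * 218, "Cs": 0.0021 * 218},
                v_half=-51.7, tau_inact=100.0),
        _preset("cavmr-g240a",
                {"Ca": 218.0, "Sr": 40.6, "K": 0.0036 * 218, "Cs": 0.0021 * 218},
                v_half=-51.7),
        _preset("cavmr-d7m", {"Ca": 144.0, "Sr": 20.7}, v_half=-51.7),
        _preset("cavmr-pp", {"Ca": 13.8, "Sr": 24.5, "K": 0.95, "Cs": 0.57},
                v_half=-51.7),
        _preset("navpp-wt",
                {"Ca": 0.308, "Sr": 0.38, "K": 0.16, "Cs": 0.0052},
                v_half=-17.11, tau_inact=100.0, tau_deact=0.5),
        _preset("navpp-t232a",
                {"Ca": 0.308, "Sr": 0.38, "K": 0.16, "Cs": 0.0052},
                v_half=-17.11),
        _preset("navpp-mr",
                {"Ca": 215.0, "Sr": 86.3, "K": 0.0045 * 215, "Cs": 0.0135 * 215},
                v_half=-17.11),
    ]
}


def step_protocol(
    levels: Sequence[float],
    holding_V: float = -140.0,
    pre_ms: float = 10.0,
    step_ms: float = 100.0,
    post_ms: float = 50.0,
    sample_rate_khz: float = 20.0,
) -> VoltageProtocol:
    """Step series from holding: hold / test step / hold; sweeps vary the
    test level. The test step is segment index 1."""
    segments = (
        const_segment("hold", holding_V, pre_ms),
        const_segment("step", levels[0], step_ms),
        const_segment("hold", holding_V, post_ms),
    )
    table = tuple({1: (lv, lv)} for lv in levels)
    return VoltageProtocol(segments, holding_V, sample_rate_khz, table)


def ramp_protocol(
    ramp_from: float = -80.0,
    ramp_to: float = 80.0,
    ramp_ms: float = 100.0,
    depol_V: float = -20.0,
    depol_ms: float = 10.0,
    holding_V: float = -140.0,
    pre_ms: float = 10.0,
    sample_rate_khz: float = 50.0,
) -> VoltageProtocol:
    """Ramp through the reversal potential, preceded by a short
    depolarization that opens the channel. The ramp is segment index 2."""
    segments = (
        const_segment("hold", holding_V, pre_ms),
        const_segment("step", depol_V, depol_ms),
        Segment("ramp", ramp_from, ramp_to, ramp_ms),
        const_segment("hold", holding_V, pre_ms),
    )
    return VoltageProtocol(segments, holding_V, sample_rate_khz)


def tail_protocol(
    prepulse_levels: Sequence[float],
    repolarization_V: float = -140.0,
    holding_V: float = -140.0,
    pre_ms: float = 10.0,
    prepulse_ms: float = 150.0,
    repol_ms: float = 100.0,
    sample_rate_khz: float = 20.0,
) -> VoltageProtocol:
    """Prepulse/tail protocol: hold / conditioning prepulse / fixed
    repolarization. Sweeps vary the prepulse level (segment index 1)."""
    segments = (
        const_segment("hold", holding_V, pre_ms),
        const_segment("step", prepulse_levels[0], prepulse_ms),
        const_segment("step", repolarization_V, repol_ms),
    )
    table = tuple({1: (lv, lv)} for lv in prepulse_levels)
    return VoltageProtocol(segments, holding_V, sample_rate_khz, table)


def _gate_series(
    command: np.ndarray, dt: float, channel: SimChannelSpec
) -> np.ndarray:
    """Activation x inactivation product m(t) * h(t) along the command."""
    m_inf = boltzmann_activation(command, channel.gating)
    m = np.empty_like(command)
    # Gate state is left-continuous: the current at sample i is carried by
    # the gate value reached at the *start* of that sampling interval, so a
    # voltage jump produces an instantaneous tail proportional to the gate
    # at the end of the preceding segment (the quantity tail analysis uses).
    m_state = float(m_inf[0])  # steady state at the initial (holding) level
    decay_act = math.exp(-dt / channel.tau_act)
    decay_deact = math.exp(-dt / channel.tau_deact)
    for i, target in enumerate(m_inf):
        m[i] = m_state
        decay = decay_act if target > m_state else decay_deact
        m_state = target + (m_state - target) * decay
    if math.isinf(channel.tau_inact):
        return m
    h = np.empty_like(command)
    h_state = 1.0
    decay_inact = math.exp(-dt / channel.tau_inact)
    for i, v in enumerate(command):
        h[i] = h_state
        target = 0.0 if v > channel.inact_threshold else 1.0
        h_state = target + (h_state - target) * decay_inact
    return m * h


def simulate(
    protocol: VoltageProtocol,
    channel: SimChannelSpec,
    pipette: Solution,
    bath: Solution,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
) -> list[CurrentTrace]:
    """Simulate all sweeps of a protocol; returns one trace per sweep.

    Determinism: with the default generator (seeded from
    ``channel.seed``) identical specs and protocols produce identical
    traces. A caller-supplied ``rng`` advances across calls, giving fresh
    but reproducible noise within a session.
    """
    if rng is None:
        rng = np.random.default_rng(channel.seed)
    dt = 1.0 / protocol.sample_rate_khz
    block = 1.0
    if channel.ca_block_ic50 is not None:
        block = 1.0 / (1.0 + bath.get("Ca") / channel.ca_block_ic50)
    traces = []
    for sweep in range(protocol.n_sweeps):
        time, command, seg_table = protocol.command(sweep)
        try:
            ionic = ghk_current(command, channel.perms, pipette, bath, constants)
            ionic = np.asarray(ionic, dtype=float)
        except ModelError:
            import warnings

            warnings.warn(
                f"no permeant ion shared by channel and solutions "
                f"({pipette.label} / {bath.label}); simulating zero flux",
                stacklevel=2,
            )
            ionic = np.zeros_like(command)
        gate = _gate_series(command, dt, channel) if channel.G_scale else 0.0
        current = channel.G_scale * block * gate * ionic
        current = current + channel.leak_conductance * command
        if channel.noise_sd > 0:
            current = current + rng.normal(0.0, channel.noise_sd, len(command))
        traces.append(
            CurrentTrace(
                time=time,
                command_V=command,
                current=current,
                sample_rate_khz=protocol.sample_rate_khz,
                metadata={
                    "channel": channel.label,
                    "pipette": pipette.label,
                    "bath": bath.label,
                    "seed": channel.seed,
                    "sweep": sweep,
                    "segments": seg_table,
                    "leak_subtracted": False,
                },
            )
        )
    return traces


def _scaled_protocol(protocol: VoltageProtocol, n_sub: int) -> VoltageProtocol:
    """Sub-sweep protocol: excursions from holding scaled by 1/n_sub."""
    hold = protocol.holding_V

    def scale(v: float) -> float:
        return hold + (v - hold) / n_sub

    segments = tuple(
        Segment(s.kind, scale(s.v_start), scale(s.v_end), s.duration_ms)
        if s.kind == "ramp" or s.v_end != hold
        else s
        for s in protocol.segments
    )
    table = tuple(
        {i: (scale(v0), scale(v1)) for i, (v0, v1) in row.items()}
        for row in protocol.sweep_table
    )
    return VoltageProtocol(segments, hold, protocol.sample_rate_khz, table)


def simulate_pn_leak_family(
    protocol: VoltageProtocol,
    channel: SimChannelSpec,
    pipette: Solution,
    bath: Solution,
    n_sub: int = 10,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> list[tuple[CurrentTrace, list[CurrentTrace]]]:
    """Main sweep plus P/N sub-sweeps for every sweep of the protocol.

    Sub-sweeps use 1/n_sub-scaled voltage excursions from the holding
    potential with the channel conductance zeroed (the sub-threshold
    assumption of the P/10 protocol), identical leak, and fresh noise.
    """
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    rng = np.random.default_rng(channel.seed)
    mains = simulate(protocol, channel, pipette, bath, constants, rng=rng)
    sub_channel = replace(channel, G_scale=0.0)
    sub_protocol = _scaled_protocol(protocol, n_sub)
    out = []
    for sweep, main in enumerate(mains):
        subs = []
        for _ in range(n_sub):
            sub = simulate(
                sub_protocol, sub_channel, pipette, bath, constants, rng=rng
            )[sweep]
            sub.metadata["n_sub"] = n_sub
            subs.append(sub)
        out.append((main, subs))
    return out


def mole_fraction(na_mM: float, ca_mM: float) -> float:
    """f_Ca = [Ca]out / ([Ca]out + [Na]out)."""
    total = na_mM + ca_mM
    if total <= 0:
        raise ValueError("mole fraction undefined for zero total cation")
    return ca_mM / total


def generate_mole_fraction_series(
    channel: SimChannelSpec,
    na_ca_pairs: Sequence[tuple[float, float]],
    protocol: VoltageProtocol,
    pipette: Solution,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> list[dict]:
    """Simulate one trace set per bath Na/Ca composition.

    Returns a list of dicts with keys ``f_ca``, ``bath``, ``traces``;
    f_Ca is attached to each trace's metadata as well.
    """
    rng = np.random.default_rng(channel.seed)
    out = []
    for na, ca in na_ca_pairs:
        if na < 0 or ca < 0:
            raise ValueError("concentrations must be nonnegative")
        f_ca = mole_fraction(na, ca)
        bath = Solution(
            f"mole-fraction-{na:g}:{ca:g}", {"Na": na, "Ca": ca}, role="bath"
        )
        traces = simulate(protocol, channel, pipette, bath, constants, rng=rng)
        for t in traces:
            t.metadata["f_ca"] = f_ca
        out.append({"f_ca": f_ca, "bath": bath, "traces": traces})
    return out
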