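"""Boltzmann activation model, tail-current extraction and G-V fitting.

Voltage dependence of activation is summarized by the two-state Boltzmann
relation

    G(V) / G_max = 1 / (1 + exp(-(V - V_half) / k)),

where V_half is the half-activation potential (mV) and k > 0 the slope
factor (mV). Activation curves are built from deactivation tail currents:
after a conditioning prepulse the membrane is stepped to a fixed
repolarization potential, and the instantaneous tail amplitude there is
proportional to the open probability reached during the prepulse.

The fit routine performs nonlinear least squares with a free amplitude and
(by default) a free additive baseline. The baseline term absorbs the
residual open probability at the repolarization potential: when tails are
collected at a potential where the channel is not fully shut (e.g. -60 mV
for a channel with V_half near -17 mV), peak-minus-baseline amplitudes are
offset by a constant, and fitting with a free baseline recovers V_half
exactly in the noiseless limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BoltzmannParams",
    "ActivationCurve",
    "BoltzmannFit",
    "boltzmann_activation",
    "extract_tail_amplitudes",
    "activation_curve_from_tails",
    "fit_boltzmann",
]


@dataclass(frozen=True)
class BoltzmannParams:
    """Midpoint, slope factor and amplitude of a Boltzmann activation curve."""

    V_half: float  # mV
    k_slope: float = 8.0  # mV, > 0
    G_max: float = 1.0  # > 0

    def __post_init__(self) -> None:
        if self.k_slope <= 0:
            raise ValueError(f"k_slope must be > 0 mV, got {self.k_slope}")
        if self.G_max <= 0:
            raise ValueError(f"G_max must be > 0, got {self.G_max}")


@dataclass
class ActivationCurve:
    """Normalized conductance-voltage data (G/G_max vs prepulse potential)."""

    prepulse_V: np.ndarray
    G_over_Gmax: np.ndarray
    n_cells: int = 1
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.prepulse_V = np.asarray(self.prepulse_V, dtype=float)
        self.G_over_Gmax = np.asarray(self.G_over_Gmax, dtype=float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.prepulse_V.shape:
                raise ValueError("sem length must match prepulse_V")
        if self.prepulse_V.shape != self.G_over_Gmax.shape:
            raise ValueError("prepulse_V and G_over_Gmax must have equal length")


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted Boltzmann parameters with asymptotic standard errors."""

    params: BoltzmannParams
    baseline: float
    se_V_half: float
    se_k_slope: float
    residual_norm: float
    converged: bool


def boltzmann_activation(V, params: BoltzmannParams):
    """Open fraction 1 / (1 + exp(-(V - V_half)/k)); vectorized in V."""
    v = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v - params.V_half) / params.k_slope))
    return out if out.ndim else float(out)


class ProtocolMismatchError(ValueError):
    """Trace lacks the expected repolarization segment."""


def _find_repol_segment(trace, repolarization_V: float, atol: float = 1e-6):
    """Locate (repol segment, preceding prepulse segment) in trace metadata.

    The repolarization segment is the last constant segment at the stated
    potential that follows at least one other segment.
    """
    segments = trace.metadata.get("segments")
    if not segments:
        raise ProtocolMismatchError("trace carries no segment metadata")
    for i in range(len(segments) - 1, 0, -1):
        seg = segments[i]
        if seg["kind"] != "ramp" and abs(seg["v_end"] - repolarization_V) <= atol:
            return seg, segments[i - 1]
    raise ProtocolMismatchError(
        f"no repolarization segment at {repolarization_V} mV found"
    )


def extract_tail_amplitudes(
    traces: Sequence,
    repolarization_V: float,
    window_ms: float = 10.0,
) -> list[tuple[float, float]]:
    """Tail amplitudes versus prepulse potential.

    For each trace the amplitude is the peak deviation of the current from
    the post-decay baseline within ``window_ms`` after the repolarization
    onset; the baseline is the mean over the final 10% of the
    repolarization segment. Amplitudes are signed relative to the
    dominant tail polarity of the sweep set: tails of the majority
    polarity are positive, inverted tails (prepulses below the foot of
    the activation curve when the repolarization potential itself opens a
    small channel fraction) come out negative. This keeps the amplitude
    a linear function of the prepulse open probability. Returns
    (prepulse_V, amplitude) pairs sorted by prepulse potential.
    """
    raw = []
    for trace in traces:
        seg, prev = _find_repol_segment(trace, repolarization_V)
        i0, i1 = seg["start"], seg["stop"]
        current = trace.current[i0:i1]
        n = len(current)
        if n < 10:
            raise ProtocolMismatchError("repolarization segment too short")
        baseline = float(np.mean(current[-max(1, n // 10):]))
        n_window = max(1, int(round(window_ms * trace.sample_rate_khz)))
        window = current[: min(n_window, n)] - baseline
        peak = float(window[np.argmax(np.abs(window))])
        raw.append((float(prev["v_end"]), peak))
    dominant = max(raw, key=lambda p: abs(p[1]))[1]
    polarity = 1.0 if dominant >= 0 else -1.0
    return sorted((v, polarity * a) for v, a in raw)


def activation_curve_from_tails(
    pairs: Sequence[tuple[float, float]],
    reference_G_max: float | None = None,
    n_cells: int = 1,
) -> ActivationCurve:
    """Normalize tail amplitudes to G/G_max.

    By default the maximum amplitude within the series defines G_max; an
    external ``reference_G_max`` may be supplied instead (used when several
    conditions share one normalization reference, e.g. normalizing every
    Ca-concentration series by the 4 mM condition's maximum).
    """
    v = np.array([p[0] for p in pairs], dtype=float)
    a = np.array([p[1] for p in pairs], dtype=float)
    gmax = float(np.max(a)) if reference_G_max is None else float(reference_G_max)
    if gmax <= 0:
        raise ValueError("nonpositive normalization reference")
    return ActivationCurve(prepulse_V=v, G_over_Gmax=a / gmax, n_cells=n_cells)


def _model_free_baseline(v, v_half, k, gmax, baseline):
    return baseline + gmax / (1.0 + np.exp(-(v - v_half) / k))


def fit_boltzmann(
    curve: ActivationCurve,
    init: BoltzmannParams | None = None,
    free_baseline: bool = True,
) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of an activation curve.

    Initialization: V_half from linear interpolation of the half-maximum
    crossing, k = 8 mV, G_max = data range. Requires at least 4 distinct
    prepulse potentials. Set ``free_baseline=False`` to pin the baseline
    at 0 (pure two-parameter-shape fit plus amplitude).
    """
    v = curve.prepulse_V
    g = curve.G_over_Gmax
    if len(np.unique(v)) < 4:
        raise ValueError("need >= 4 distinct prepulse potentials to fit")
    if np.ptp(g) == 0:
        raise ValueError("degenerate activation data: all values equal")

    if init is None:
        half = (g.min() + g.max()) / 2.0
        order = np.argsort(v)
        v_s, g_s = v[order], g[order]
        v_half0 = float(np.interp(half, g_s, v_s)) if np.all(np.diff(g_s) >= 0) \
            else float(v_s[np.argmin(np.abs(g_s - half))])
        init = BoltzmannParams(V_half=v_half0, k_slope=8.0,
                               G_max=float(np.ptp(g)))

    if free_baseline:
        p0 = [init.V_half, init.k_slope, init.G_max, float(g.min())]
        model = _model_free_baseline
    else:
        p0 = [init.V_half, init.k_slope, init.G_max]

        def model(vv, v_half, k, gmax):
            return _model_free_baseline(vv, v_half, k, gmax, 0.0)

    try:
        import warnings as _warnings
        from scipy.optimize import OptimizeWarning

        with _warnings.catch_warnings():
            # noiseless data fits exactly; the singular covariance there is
            # expected and the SEs are reported as nan
            _warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(
                model, v, g, p0=p0, maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        converged = True
    except RuntimeError as exc:
        raise RuntimeError(f"Boltzmann fit failed to converge: {exc}") from exc

    resid = g - model(v, *popt)
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.diag(pcov))
    return BoltzmannFit(
        params=BoltzmannParams(
            V_half=float(popt[0]), k_slope=float(abs(popt[1])),
            G_max=float(abs(popt[2])),
        ),
        baseline=float(popt[3]) if free_baseline else 0.0,
        se_V_half=float(ses[0]),
        se_k_slope=float(ses[1]),
        residual_norm=float(np.linalg.norm(resid)),
        converged=converged,
    )
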