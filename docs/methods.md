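# Methods

## Permeation model

The package models channel current as a sum of independent
Goldman–Hodgkin–Katz (constant-field) fluxes over the permeant cations.
With ψ = VF/RT (V in mV, inside minus outside; outward current
positive), each ion X of valence z contributes

    I_X = P_X · z² · ψ · ([X]in − [X]out · e^(−zψ)) / (1 − e^(−zψ)),

in arbitrary current units (the absolute P_Na sets the scale; only
ratios matter for selectivity). Activities are identified with
concentrations: the inverse expressions used in the field are written in
concentrations, and applying an activity correction on one side of a
round trip and not the other would break the identity that makes the
analysis self-consistent. Anions, buffers (HEPES, EGTA, glucose) and
NMDG⁺ are impermeant; they are retained in solution records so printed
recipes can be audited, but carry no flux. Temperature defaults to
298.1 K (25 °C), giving RT/F = 25.69 mV, a monovalent Nernst slope of
59.15 mV/decade and a divalent slope of 29.57 mV/decade.

Each per-ion flux factor is strictly increasing in V for nonnegative
concentrations, so the summed current has at most one zero. The
reversal potential is found by Brent's method on [−200, +200] mV
(xtol 10⁻¹² mV); the solver reports the bracket, iteration count and
residual current, and raises with both end-point currents when no sign
change exists (e.g. a one-sided ion with no counter-flux).

**V = 0 singularity.** The factor ψ(Cin − Cout·e^(−zψ))/(1 − e^(−zψ))
has a removable singularity at 0. For |zψ| < 10⁻⁴ it is evaluated by its
second-order series (ΔC + a(Cin+Cout)/2 + a²ΔC/12)/z with a = zψ,
ΔC = Cin − Cout; elsewhere with `expm1` to avoid cancellation. The two
branches agree to better than 10⁻⁹ at the switch point.

## Inverse (zero-current) expressions

The two-ion Na/Ca expression,

    P_Ca/P_Na = −(A_Na · (1 − e^(−2x))) / (4 · A_Ca · (1 − e^(−x))),
    x = uE_rev,  A_Na = [Na]in − [Na]out·e^(−x),
    A_Ca = [Ca]in − [Ca]out·e^(−2x),

is evaluated through the exact factorization
(1 − e^(−2x))/(1 − e^(−x)) = 1 + e^(−x), which is regular at E_rev = 0
(where the factor equals its analytic limit 2). The same routine serves
Sr²⁺.

The extended three-ion expression for a monovalent test cation M is
re-derived here rather than transcribed. Setting the summed current of
{Na⁺, M⁺, Ca²⁺} to zero at E_rev and dividing by the common factor
ψ/(1 − e^(−x)) gives

    A_Na + (P_M/P_Na)·A_M + 4·(P_Ca/P_Na)·A_Ca/(1 + e^(−x)) = 0,

hence

    P_M/P_Na = −(A_Na + 4·(P_Ca/P_Na)·A_Ca/(1 + e^(−x))) / A_M.

Expanding the bracketed published form term by term reproduces this
grouping exactly (the test suite asserts numerical identity against a
literal rendering over random arguments). With the Ca terms removed it
reduces to the classic two-ion bi-ionic formula [Na]in·e^(x)/[M]out.

Because forward model and inverse expressions share the same flux form
and the z² = 4, e^(−2x) divalent convention, solve-then-substitute round
trips are exact to solver precision. This is the package's primary
validation surface: published ratios (Ca:Na 218, 144, 0.308, 215; K:Na
0.16) are used as ground-truth parameters and must be recovered to
≤10⁻⁶ relative under the corresponding recording solutions.

## Gating model and tail-current analysis

Steady-state activation is a two-state Boltzmann,
m∞(V) = 1/(1 + e^(−(V−V½)/k)). The slope factor k is not published for
these channels; the simulator default is k = 8 mV, a typical BacNav
value, and fitting always treats k as free, so no analysis result
depends on the default. Published midpoints used in presets:
−51.7 mV (CavMr) and −17.11 mV (NavPp T232A).

The simulated gate relaxes mono-exponentially toward m∞(V) with τ_act
(5 ms) when opening and τ_deact (2 ms) when closing; an optional
inactivation gate relaxes toward 0 above a threshold (−40 mV) with
τ_inact (100 ms for wild-type presets, ∞ for the slowly-inactivating
G240A/T232A-style presets). All time constants are illustrative — none
are published — and no analysis surface depends on them. The gate is
sampled left-continuously: the current at a sample uses the gate value
at the start of that sampling interval, so a voltage step produces an
instantaneous tail current exactly proportional to the open probability
reached during the prepulse, which is the quantity tail analysis
measures.

Tail amplitudes are peak-minus-baseline: the extremal deviation of the
current from the post-decay baseline (mean of the final 10 % of the
repolarization segment) within a 10 ms window after repolarization
onset. This is exact for the simulator's mono-exponential tails; it is
a deliberate dialect — no exponential extrapolation to the
repolarization instant is attempted. Amplitudes are signed relative to
the dominant tail polarity of the sweep set, so prepulses below the
foot of the activation curve (possible when the repolarization
potential itself sustains a small open fraction, as with tails at
−60 mV) yield negative values and the amplitude stays linear in the
prepulse open probability.

The Boltzmann fit is nonlinear least squares (scipy `curve_fit`,
Levenberg–Marquardt, tolerances 10⁻¹⁴) over V½, k, G_max and — by
default — a free additive baseline. The baseline term absorbs the
constant offset introduced by the residual open probability at the
repolarization potential; without it, V½ recovered from −60 mV tails
would be biased by ~0.1 mV. Initialization is deterministic: V½ from
linear interpolation of the half-maximum crossing, k = 8 mV, G_max from
the data range. Curves are fitted after averaging/normalizing (fit the
averaged curve, not per-cell parameters); a per-cell path is available
by fitting each cell's curve separately. Normalization by an external
reference G_max (e.g. one condition's maximum shared across a
concentration series) is supported via `activation_curve_from_tails`.

## Synthetic recordings

One sweep is I(t) = G·m(t)·h(t)·I_GHK(V(t)) + g_leak·V(t) + ε(t), with
white Gaussian noise ε seeded through `numpy.random.default_rng`;
identical channel spec + protocol ⇒ bit-identical traces. Capacitive
transients are not simulated (analysis operates on
capacitance-compensated recordings), noise has no 1/f or line
component, and series-resistance errors are out of scope. A
phenomenological Ca²⁺-block factor 1/(1 + [Ca]out/IC₅₀) can be enabled
per channel spec (off by default); it emulates the qualitative
suppression of current by external Ca²⁺ seen in NavPp without claiming
a mechanism.

Protocols are piecewise hold/step/ramp segments with per-sweep level
overrides, sampled at 20–50 kHz. Defaults follow the recording
conventions modelled: holding −140 mV; tail repolarization −140 mV
(CavMr) or −60 mV (NavPp); ramps chosen to bracket the reversal
potential.

**P/N leak subtraction.** The P/10 family delivers n = 10 sub-sweeps
whose voltage excursions from the −140 mV holding level are scaled by
1/n, with channel conductance zeroed (sub-threshold assumption) and the
same ohmic leak. Subtraction removes the holding-level leak estimate
plus the summed sub-sweep deviations; for a noiseless linear leak this
is exact to machine precision. With per-sample noise sd σ the corrected
trace has residual sd σ·√(1+n) (the summed sub-sweeps contribute n·σ²),
which the Monte-Carlo test confirms.

**Mole-fraction series.** Baths sweep the NaCl/CaCl₂ ratios 135/0,
108/18, 81/36, 54/54, 27/82, 0/90 mM at fixed pipette, protocol and
channel; f_Ca = [Ca]out/([Ca]out + [Na]out) is attached to metadata.
The summary takes the peak inward current at a configurable test
potential (default −20 mV), normalizes to the series maximum, and
declares a non-monotonicity (anomalous mole-fraction effect) only when
an interior point lies below both neighbors by more than a tolerance
(default 2× the noise sd of the normalized amplitudes, estimated from
second differences). The single-site GHK model is deliberately
incapable of producing an anomalous mole-fraction minimum, so the
monotone verdict for the Ca-selective preset is a structural property,
not a fitted one.

## Analysis pipeline conventions

- Ramp reversal potentials interpolate the command voltage at the
  single zero crossing of the (optionally moving-average-smoothed)
  current; zero or multiple crossings raise with the crossing count.
  Interpolation is in voltage, not time (identical for linear ramps).
- Permeability ratios are computed per cell and then averaged;
  tables report mean ± SEM (sd with n−1 denominator over √n) and n,
  with SEM reported as 0 when n = 1. Ratios expressed against Ca
  instead of Na (the convention used for highly Ca-selective channels'
  monovalent ratios) are carried as footnotes.
- The E_rev-vs-log₁₀[Ca]out slope regression supports both the full
  concentration series and a restricted subset (named preset
  `{4, 10, 20}` mM); the theoretical divalent comparator
  RT·ln10/2F ≈ 29.6 mV/decade is available from
  `nernst_slope_per_decade(2)`.
- I-V curves measure the signed peak (extremum) or steady-state mean of
  the test step, optionally normalized so the reference step maps to
  exactly 1 (or −1 under the inward-reference convention).

## Filter-sequence accounting

Filters are 7-residue windows with local 1–7 numbering anchored to a
parent offset (CavMr: 183 → Thr1…Asp7). Mutation codes (G4D, T6S, …)
use local numbering; full-protein codes are accepted only with an
explicit parent offset, since the two conventions are ambiguous
otherwise. Charge accounting counts D and E as −1 (no filter residue
here is positively charged; histidine is never counted) — this
reproduces the canonical tetramer counts of 8 (CavMr, `TLEGWVD`×4) and
12 (CavAb, `TLDDWSD`×4). Heteromeric assemblies (e.g. the four distinct
subdomain filters of a mammalian Cav) are summed one subunit each; the
subdomain strings themselves are user-supplied, as only the filter
strings printed in running text ship as fixtures.

## What the synthetic data does and does not show

The generator reproduces the structural assumptions of the analysis —
GHK-shaped instantaneous I-V, Boltzmann gating, mono-exponential
kinetics, linear leak, white noise — so passing tests demonstrate that
the inference chain is internally consistent and numerically exact
under those assumptions. Real recordings violate them in ways the
simulator does not model: ionic block and anomalous mole-fraction
behavior (multi-ion pores), voltage errors from series resistance,
capacitive residue, drifting leak, non-Gaussian noise. Recovery under
synthetic data therefore validates the code, not the constant-field
assumption itself. Two known mismatches with the measurements this
package models are deliberate: the high-Ca "no outward current at
+100 mV" observation corresponds in the model to an outward current
<1 % of the peak inward current (not literally zero), and the slope
inflation caused by an unmeasurable outward current at 40 mM Ca²⁺ is a
measurement artifact the model does not attempt to reproduce.

## Problem sizes

Default test/validation sizes: tail protocols of 15–19 sweeps at
20 kHz (~260 ms each); ramp protocols of ~130 ms at 50 kHz; 20 random
permeability sets for oracle-equivalence and end-to-end recovery; 100
seeds for the noisy Boltzmann recovery study; 30–40 seeds for
noise-scaling checks. The full suite runs in a few seconds on one core.
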