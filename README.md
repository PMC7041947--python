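# biionic

Quantitative ion-selectivity analysis for homotetrameric prokaryotic
voltage-gated channels (BacNav/Cav family), built around the
Goldman–Hodgkin–Katz (GHK) constant-field model, plus a synthetic
whole-cell voltage-clamp generator so the whole inference chain can be
exercised and validated without laboratory recordings.

## Who this is for

Electrophysiologists and modellers who quantify how strongly a channel
prefers one cation over another — e.g. the Ca²⁺-selective channel CavMr
from *Meiothermus ruber* (selectivity filter `TLEGWVD`) versus the
Na⁺-preferring NavPp from *Plesiocystis pacifica* (`TLEDWTD`) — from
bi-ionic reversal potentials, and who want the entire pipeline (leak
subtraction, ramp analysis, GHK inversion, Boltzmann gating fits,
filter-sequence bookkeeping) as tested, reusable code.

## The model

Under the constant-field assumption, each permeant cation X with valence
z carries current

I_X(V) = P_X · z² · ψ · ([X]ᵢₙ − [X]ₒᵤₜ·e^(−zψ)) / (1 − e^(−zψ)),  ψ = VF/RT,

and the reversal potential E_rev is the unique zero of the summed
currents. Under a Na⁺ᵢₙ/Ca²⁺ₒᵤₜ bi-ionic condition the zero-current
condition inverts to the two-ion expression

P_Ca/P_Na = −([Na]ᵢₙ − [Na]ₒᵤₜ·e^(−uE)) (1 − e^(−2uE)) /
            [4 ([Ca]ᵢₙ − [Ca]ₒᵤₜ·e^(−2uE)) (1 − e^(−uE))],  u = F/RT,

(the same form serves Sr²⁺), and with a third, monovalent test cation M
present to the extended expression for P_M/P_Na (see
`docs/methods.md` for the derivation). Temperature defaults to 298.1 K.
Voltage dependence of activation follows a Boltzmann relation
G/G_max = 1/(1 + e^(−(V−V½)/k)) fitted to tail-current amplitudes.

## Worked example

```python
from biionic import (PermeabilitySet, get_solution,
                     reversal_potential, pca_pna_from_erev)

pipette = get_solution("high-na-pipette")   # 150 mM Na+ inside
bath = get_solution("ca10-nmdg-bath")       # 10 mM Ca2+ in NMDG outside

perms = PermeabilitySet(ratios={"Ca": 218.0})   # highly Ca-selective
report = reversal_potential(perms, pipette, bath)
print(f"E_rev = {report.E_rev:.2f} mV")
ratio = pca_pna_from_erev(report.E_rev, pipette["Na"], bath["Na"],
                          pipette["Ca"], bath["Ca"])
print(f"P_Ca/P_Na = {ratio:.1f}")
```

prints

```
E_rev = 50.50 mV
P_Ca/P_Na = 218.0
```

A channel with P_Ca/P_Na = 218 under 150 mM internal Na⁺ and 10 mM
external Ca²⁺ reverses at +50.5 mV, and substituting that reversal
potential back into the zero-current expression returns the ratio that
generated it — the self-consistency on which the package's validation
rests.

The same round trip through simulated data:

```bash
biionic demo reproduce-paper
biionic sim run --preset cavmr-g240a --protocol ramp-iv \
    --bath ca10-nmdg-bath --seed 7 --out traces.csv
biionic analyze erev traces.csv
```

## Layout

- `biionic.solutions` — ionic solutions (all printed recipes catalogued), Nernst potentials
- `biionic.ghk` — GHK flux model, reversal-potential solver, inverse permeability expressions
- `biionic.gating` — Boltzmann activation, tail-current extraction, curve fitting
- `biionic.simulate` — voltage protocols and synthetic whole-cell recordings
- `biionic.analysis` — P/N leak subtraction, ramp/I-V analysis, permeability tables, slope fits, mole-fraction summaries
- `biionic.filters` — selectivity-filter renumbering, mutations, charge counts, frequency matrices
- `biionic.io` / `biionic.cli` — trace CSV format, pipeline runner, command-line interface
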