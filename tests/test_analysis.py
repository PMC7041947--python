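import dataclasses
import math

import numpy as np
import pytest

from biionic import (
    CellRecord,
    PermeabilitySet,
    Solution,
    build_iv_curve,
    erev_concentration_slope,
    extract_erev_from_ramp,
    get_solution,
    mole_fraction_summary,
    nernst_slope_per_decade,
    pca_pna_from_erev,
    permeability_table,
    pn_subtract,
    ramp_protocol,
    reversal_potential,
    simulate,
    simulate_pn_leak_family,
    step_protocol,
    generate_mole_fraction_series,
)
from biionic.analysis import AlignmentError, CrossingError, NormalizationError
from conftest import fast_gating_channel


class TestPNSubtract:
    def test_synthetic_linear_leak_fully_removed(self, high_na_pipette,
                                                 ca10_bath):
        # leak 1 unit/mV; after subtraction the corrected ramp current has
        # no residual linear dependence on voltage beyond the channel term
        channel = fast_gating_channel({"Ca": 218.0}, leak_conductance=1.0)
        fam = simulate_pn_leak_family(ramp_protocol(), channel,
                                      high_na_pipette, ca10_bath, n_sub=10)
        main, subs = fam[0]
        corrected = pn_subtract(main, subs, 10)
        pure = simulate(ramp_protocol(),
                        dataclasses.replace(channel, leak_conductance=0.0),
                        high_na_pipette, ca10_bath)[0]
        residual = corrected.current - pure.current
        seg = main.metadata["segments"][2]  # ramp
        slope = np.polyfit(main.command_V[seg["start"]:seg["stop"]],
                           residual[seg["start"]:seg["stop"]], 1)[0]
        assert abs(slope) < 1e-6
        assert corrected.metadata["leak_subtracted"] is True

    def test_shape_mismatch_raises(self, cavmr, high_na_pipette, ca10_bath):
        fam = simulate_pn_leak_family(ramp_protocol(), cavmr,
                                      high_na_pipette, ca10_bath, n_sub=2)
        main, subs = fam[0]
        short = dataclasses.replace(
            subs[0],
            time=subs[0].time[:-1], command_V=subs[0].command_V[:-1],
            current=subs[0].current[:-1],
        )
        with pytest.raises(AlignmentError):
            pn_subtract(main, [short], 1)


class TestRampErev:
    def test_matches_analytic_solver(self, high_na_pipette, ca10_bath):
        channel = fast_gating_channel({"Ca": 218.0})
        trace = simulate(ramp_protocol(), channel, high_na_pipette,
                         ca10_bath)[0]
        e = extract_erev_from_ramp(trace)
        truth = reversal_potential(channel.perms, high_na_pipette,
                                   ca10_bath).E_rev
        assert abs(e - truth) <= 0.1

    def test_all_positive_window_raises_no_crossing(self):
        channel = fast_gating_channel({"Ca": 218.0})
        pip = Solution("p", {"NMDG": 150}, role="pipette")  # nothing inside
        bath = get_solution("ca10-nmdg-bath")
        trace = simulate(ramp_protocol(), channel, pip, bath)[0]
        with pytest.raises(CrossingError, match="0 crossings"):
            extract_erev_from_ramp(trace)

    def test_smoothing_reduces_estimator_scatter(self, high_na_pipette,
                                                 ca10_bath):
        channel = fast_gating_channel({"Ca": 218.0}, noise_sd=2.0)
        raw, smooth = [], []
        for seed in range(40):
            spec = dataclasses.replace(channel, seed=seed)
            trace = simulate(ramp_protocol(), spec, high_na_pipette,
                             ca10_bath)[0]
            raw.append(extract_erev_from_ramp(trace, smoothing=5))
            smooth.append(extract_erev_from_ramp(trace, smoothing=201))
        assert np.std(smooth) < np.std(raw)


class TestIVCurve:
    def test_reference_point_normalizes_to_one(self, cavmr, high_na_pipette,
                                               ca10_bath):
        sweeps = simulate(step_protocol(levels=[-40.0, -20.0, 0.0]), cavmr,
                          high_na_pipette, ca10_bath)
        curve = build_iv_curve(sweeps, normalization_ref=(0.0, 0.1))
        assert curve.I[curve.V == 0.0][0] == 1.0

    def test_missing_reference_raises(self, cavmr, high_na_pipette,
                                      ca10_bath):
        sweeps = simulate(step_protocol(levels=[-40.0]), cavmr,
                          high_na_pipette, ca10_bath)
        with pytest.raises(NormalizationError):
            build_iv_curve(sweeps, normalization_ref=(20.0, 0.1))

    def test_larger_inward_current_in_high_ca_than_high_na_bath(self, cavmr):
        pipette = get_solution("iv-pipette")
        bath_ca = get_solution("ca100-bath")
        bath_na = Solution("high-na-bath", {"Na": 150, "Cl": 150}, role="bath")
        proto = step_protocol(levels=[-20.0])
        peak = {}
        for name, bath in (("ca", bath_ca), ("na", bath_na)):
            sweep = simulate(proto, cavmr, pipette, bath)[0]
            seg = sweep.metadata["segments"][1]
            peak[name] = -np.min(sweep.current[seg["start"]:seg["stop"]])
        assert peak["ca"] > peak["na"] > 0

    def test_symmetric_na_fully_open_crosses_zero_at_zero(self):
        channel = fast_gating_channel({})
        sol_in = Solution("sym-in", {"Na": 150}, role="pipette")
        sol_out = Solution("sym-out", {"Na": 150}, role="bath")
        sweeps = simulate(step_protocol(levels=[-20.0, 0.0, 20.0]), channel,
                          sol_in, sol_out)
        curve = build_iv_curve(sweeps, measure="steady")
        assert curve.I[curve.V == 0.0][0] == pytest.approx(0.0, abs=1e-9)
        assert curve.I[curve.V == -20.0][0] < 0 < curve.I[curve.V == 20.0][0]


class TestPermeabilityTable:
    def _records(self, e_revs, ratio="P_Ca/P_Na", channel="cavmr-g240a"):
        pip = get_solution("high-na-pipette")
        bath = get_solution("ca10-nmdg-bath")
        return [
            CellRecord(f"cell{i}", channel, ratio, e, pip, bath)
            for i, e in enumerate(e_revs)
        ]

    def test_monte_carlo_recovery_with_erev_noise(self):
        pip = get_solution("high-na-pipette")
        bath = get_solution("ca10-nmdg-bath")
        truth = reversal_potential(
            PermeabilitySet(ratios={"Ca": 218.0}), pip, bath
        ).E_rev
        rng = np.random.default_rng(12)
        e_revs = truth + rng.normal(0, 1.0, 7)  # per-cell E_rev sd 1 mV
        rows = permeability_table(self._records(e_revs))
        assert len(rows) == 1
        row = rows[0]
        assert row.n == 7
        assert row.mean == pytest.approx(218.0, rel=0.10)

    def test_single_noiseless_cell_round_trip_with_sem_zero(self):
        pip = get_solution("high-na-pipette")
        bath = get_solution("ca10-nmdg-bath")
        e = reversal_potential(PermeabilitySet(ratios={"Ca": 144.0}),
                               pip, bath).E_rev
        bath144 = bath
        row = permeability_table(self._records([e]))[0]
        assert row.mean == pytest.approx(144.0, rel=1e-6)
        assert row.sem == 0.0 and row.n == 1

    def test_row_per_distinct_channel_ratio_pair(self):
        recs = (
            self._records([10.0, 12.0], channel="a")
            + self._records([11.0], channel="b")
        )
        rows = permeability_table(recs)
        assert len(rows) == 2
        assert {(r.channel, r.n) for r in rows} == {("a", 2), ("b", 1)}

    def test_monovalent_record_requires_pca(self):
        pip = get_solution("high-na-pipette")
        bath = get_solution("k-bath")
        rec = CellRecord("c0", "navpp", "P_K/P_Na", -40.0, pip, bath)
        with pytest.raises(ValueError, match="P_Ca/P_Na"):
            permeability_table([rec])

    def test_aggregation_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        e_revs = rng.uniform(30, 60, 9)
        row = permeability_table(self._records(e_revs))[0]
        # one-pass oracle over the same per-cell values
        vals = row.per_cell_values
        n = len(vals)
        mean = sum(vals) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
        assert row.mean == pytest.approx(mean, abs=1e-12)
        assert row.sem == pytest.approx(sd / math.sqrt(n), abs=1e-12)


class TestConcentrationSlope:
    def test_nernst_limit_slope_for_extreme_ca_selectivity(self):
        # P_Ca/P_Na = 1e6: E_rev vs log10[Ca]out over the 4/10/20 mM series
        # approaches the divalent Nernst slope RT ln10 / 2F within 1%
        pip = get_solution("high-na-pipette")
        perms = PermeabilitySet(ratios={"Ca": 1e6})
        points = [
            (c, reversal_potential(
                perms, pip, get_solution(f"ca{c}-nmdg-bath")).E_rev)
            for c in (4, 10, 20)
        ]
        fit = erev_concentration_slope(points)
        assert fit.slope == pytest.approx(nernst_slope_per_decade(2),
                                          rel=0.01)

    def test_collinear_points_give_unit_r_squared(self):
        points = [(4, 10.0), (10, 10.0 + 29.57 * math.log10(10 / 4)),
                  (20, 10.0 + 29.57 * math.log10(20 / 4))]
        fit = erev_concentration_slope(points)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_restricted_subset_selection(self):
        points = [(4, 1.0), (10, 2.0), (20, 3.0), (40, 100.0)]
        full = erev_concentration_slope(points)
        restricted = erev_concentration_slope(points, include=[4, 10, 20])
        assert restricted.included_concentrations == (4, 10, 20)
        assert full.slope > restricted.slope  # the 40 mM point inflates it

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            erev_concentration_slope([(10, 5.0)])


class TestMoleFractionSummary:
    PAIRS = [(135, 0), (108, 18), (81, 36), (54, 54), (27, 82), (0, 90)]

    def test_cavmr_series_is_monotonic(self, cavmr, high_na_pipette):
        sets = generate_mole_fraction_series(
            cavmr, self.PAIRS, step_protocol(levels=[-20.0]), high_na_pipette
        )
        summary = mole_fraction_summary(sets, measure_V=-20.0)
        assert summary["monotonic"] is True
        assert np.max(summary["normalized_amplitude"]) == 1.0
        assert np.all(np.diff(summary["normalized_amplitude"]) >= 0)

    def test_constructed_interior_dip_flagged(self):
        # hand-built series with a dip 3x the tolerance at f_Ca = 0.5
        class FakeTrace:
            def __init__(self, amp):
                self.current = np.array([0.0] * 5 + [-amp] * 10)
                self.metadata = {
                    "segments": [
                        {"kind": "hold", "v_end": -140.0, "start": 0, "stop": 5},
                        {"kind": "step", "v_end": -20.0, "start": 5, "stop": 15},
                    ]
                }

        tol = 0.05
        amps = [0.2, 0.5, 0.8 - 3 * tol, 0.8, 0.9, 1.0]
        sets = [
            {"f_ca": f, "traces": [FakeTrace(a)]}
            for f, a in zip([0, 0.2, 0.4, 0.6, 0.8, 1.0], amps)
        ]
        # move the dip to an interior point below both neighbors
        sets[2]["traces"] = [FakeTrace(0.5 - 3 * tol)]
        summary = mole_fraction_summary(sets, measure_V=-20.0, tolerance=tol)
        assert summary["monotonic"] is False
        assert summary["dip_indices"] == [2]

    def test_needs_at_least_three_fractions(self, cavmr, high_na_pipette):
        sets = generate_mole_fraction_series(
            cavmr, [(135, 0), (0, 90)], step_protocol(levels=[-20.0]),
            high_na_pipette,
        )
        with pytest.raises(ValueError):
            mole_fraction_summary(sets)


class TestEndToEndRecovery:
    def test_noiseless_pipeline_recovers_random_ratios_within_5pct(
        self, high_na_pipette, ca10_bath
    ):
        rng = np.random.default_rng(17)
        ratios = 10 ** rng.uniform(-1, math.log10(500), 20)
        # ramp chosen to bracket every reversal potential in the ratio range
        proto = ramp_protocol(ramp_from=-130.0, ramp_to=80.0)
        for ratio in ratios:
            channel = fast_gating_channel({"Ca": float(ratio)},
                                          leak_conductance=0.5)
            fam = simulate_pn_leak_family(proto, channel, high_na_pipette,
                                          ca10_bath, n_sub=10)
            main, subs = fam[0]
            corrected = pn_subtract(main, subs, 10)
            e_rev = extract_erev_from_ramp(corrected)
            recovered = pca_pna_from_erev(e_rev, 150, 0, 0, 10)
            assert recovered == pytest.approx(ratio, rel=0.05)
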