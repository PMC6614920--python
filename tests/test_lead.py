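"""Lead-cleavage quantification: integration, two-state normalization, fitting."""

import numpy as np
import pytest

from tectofit import (
    Direction,
    LeadSimSpec,
    ProtectionKind,
    call_fa_response,
    call_protections,
    fit_two_state,
    homodimer_fraction,
    integrate_band,
    normalize_two_state,
    simulate_lead_profiles,
    two_fold_ladder,
)
from tectofit.lead import position_series
from tectofit.thermo import R_KCAL_PER_K_MOL


class TestBandIntegration:
    def test_flat_trace_integrates_to_zero(self):
        assert integrate_band([5.0] * 20, (8, 12)) == 0.0

    def test_single_bin_peak(self):
        trace = np.zeros(20)
        trace[10] = 7.0
        assert integrate_band(trace, (9, 12)) == 7.0

    def test_rectangular_peak_minus_baseline(self):
        trace = np.full(20, 2.0)
        trace[8:11] = 10.0
        assert integrate_band(trace, (8, 11)) == pytest.approx((10 - 2) * 3)

    def test_negative_totals_floor_at_zero(self):
        trace = np.full(20, 5.0)
        trace[8:11] = 1.0
        assert integrate_band(trace, (8, 11)) == 0.0

    def test_window_at_trace_edge_rejected(self):
        with pytest.raises(ValueError):
            integrate_band([1.0] * 10, (0, 3), baseline_half_width=2)

    def test_lane_profile_quantification_round_trip(self, tmp_path):
        from tectofit.lead import quantify_lane_profiles, read_profile_tsv

        trace_a = np.full(30, 1.0)
        trace_a[10:13] = 6.0  # band "10": (6-1)*3 = 15
        trace_b = np.full(30, 1.0)
        trace_b[10:13] = 3.0  # band "10": (3-1)*3 = 6
        path = tmp_path / "profiles.tsv"
        path.write_text(
            "lane1\t" + "\t".join(map(str, trace_a)) + "\n"
            "lane2\t" + "\t".join(map(str, trace_b)) + "\n"
        )
        traces = read_profile_tsv(path)
        out = quantify_lane_profiles(traces, {"10": (10, 13)})
        assert out["lane1"]["10"] == pytest.approx(15.0)
        assert out["lane2"]["10"] == pytest.approx(6.0)


class TestTwoStateNormalization:
    def test_decreasing_extremes(self):
        pts = [(5.0, 1.0), (50.0, 0.6), (500.0, 0.2)]
        s = normalize_two_state(pts, Direction.DECREASING)
        fm = dict(s.points)
        assert fm[5.0] == 1.0 and fm[500.0] == 0.0
        assert fm[50.0] == pytest.approx(0.5)

    def test_increasing_midpoint(self):
        pts = [(5.0, 0.2), (50.0, 0.6), (500.0, 1.0)]
        s = normalize_two_state(pts, Direction.INCREASING)
        fm = dict(s.points)
        assert fm[5.0] == 1.0 and fm[500.0] == 0.0
        assert fm[50.0] == pytest.approx(0.5)

    def test_constant_intensity_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            normalize_two_state([(5.0, 1.0), (50.0, 1.0)], Direction.DECREASING)

    def test_clipping_property(self, rng):
        for _ in range(20):
            conc = np.sort(rng.uniform(1, 1e4, size=8))
            inten = rng.uniform(-2, 5, size=8)  # arbitrary, even negative
            if np.ptp(inten) == 0:
                continue
            s = normalize_two_state(
                list(zip(conc, np.abs(inten))), Direction.DECREASING
            )
            fm = np.array([f for _, f in s.points])
            assert np.all((fm >= 0) & (fm <= 1))


class TestTwoStateFit:
    @pytest.mark.parametrize("true_kd", [63.0, 266.0, 300.0, 1573.0])
    def test_noiseless_recovery(self, true_kd):
        spec = LeadSimSpec(
            true_Kd_noFA_nM=true_kd, true_Kd_FA_nM=true_kd,
            positions=[("10", Direction.DECREASING, 1.0, 0.2)],
            noise_sd_frac=0.0, seed=0,
        )
        profile, _, _ = simulate_lead_profiles(spec)
        series = normalize_two_state(
            position_series(profile, "10"), Direction.DECREASING, position="10"
        )
        fit = fit_two_state(series)
        assert fit.Kd_nM == pytest.approx(true_kd, rel=1e-3)

    def test_monomer_only_series_flags_no_assembly(self):
        ladder = two_fold_ladder()
        from tectofit.lead import MonomerFractionSeries

        series = MonomerFractionSeries(
            position="10",
            points=[(float(c), 1.0) for c in ladder],
            direction_used=Direction.DECREASING,
        )
        fit = fit_two_state(series)
        assert fit.no_assembly
        assert "NO_ASSEMBLY" in fit.flags

    def test_noisy_flag_on_incoherent_series(self, rng):
        ladder = two_fold_ladder()
        from tectofit.lead import MonomerFractionSeries

        series = MonomerFractionSeries(
            position="10",
            points=[(float(c), float(f)) for c, f in zip(ladder, rng.uniform(0, 1, ladder.size))],
            direction_used=Direction.DECREASING,
        )
        fit = fit_two_state(series)
        assert fit.noisy


class TestProtectionCalls:
    def test_equal_states_are_unchanged(self):
        state = {"10": 1.0, "11": 0.5, "18": 0.2}
        calls = call_protections(state, dict(state))
        assert all(c.direction is ProtectionKind.UNCHANGED for c in calls)

    def test_enhancement_at_bulge_and_protection_in_pairing(self):
        mono = {"14": 0.2, "18": 1.0, "19": 0.9, "20": 0.8, "21": 0.9, "22": 1.1}
        dimer = {"14": 1.0, "18": 0.2, "19": 0.2, "20": 0.15, "21": 0.2, "22": 0.25}
        by_pos = {c.position: c for c in call_protections(mono, dimer)}
        assert by_pos["14"].direction is ProtectionKind.ENHANCED_IN_DIMER
        for pos in ("18", "19", "20", "21", "22"):
            assert by_pos[pos].direction is ProtectionKind.PROTECTED_IN_DIMER
            assert by_pos[pos].magnitude >= 1.5

    def test_antisymmetry_under_state_swap(self, rng):
        positions = [str(i) for i in range(1, 11)]
        a = {p: float(x) for p, x in zip(positions, rng.uniform(0.05, 2.0, 10))}
        b = {p: float(x) for p, x in zip(positions, rng.uniform(0.05, 2.0, 10))}
        fwd = {c.position: c for c in call_protections(a, b)}
        rev = {c.position: c for c in call_protections(b, a)}
        swap = {
            ProtectionKind.PROTECTED_IN_DIMER: ProtectionKind.ENHANCED_IN_DIMER,
            ProtectionKind.ENHANCED_IN_DIMER: ProtectionKind.PROTECTED_IN_DIMER,
            ProtectionKind.UNCHANGED: ProtectionKind.UNCHANGED,
        }
        for p in positions:
            assert rev[p].direction is swap[fwd[p].direction]
            assert rev[p].magnitude == pytest.approx(fwd[p].magnitude)

    def test_fa_specific_calls(self):
        no_fa = {"10": 1.0, "14": 0.3}
        fa = {"10": 0.3, "14": 1.0}
        by_pos = {c.position: c for c in call_fa_response(no_fa, fa)}
        assert by_pos["10"].direction is ProtectionKind.FA_SPECIFIC_PROTECTED
        assert by_pos["14"].direction is ProtectionKind.FA_SPECIFIC_ENHANCED

    def test_mismatched_positions_rejected(self):
        with pytest.raises(ValueError):
            call_protections({"10": 1.0}, {"11": 1.0})


class TestEndToEndLigandShift:
    def test_ddg_fa_recovered_from_synthetic_profile_pairs(self):
        """+/-FA profile pairs generated at (1573, 266) nM reproduce
        RT ln(266/1573) at 293 K within +/-0.15 kcal/mol on average."""
        expected = R_KCAL_PER_K_MOL * 293.0 * np.log(266.0 / 1573.0)
        ddgs = []
        for seed in range(25):
            spec = LeadSimSpec(
                true_Kd_noFA_nM=1573.0, true_Kd_FA_nM=266.0,
                positions=[("10", Direction.DECREASING, 1.0, 0.2)],
                noise_sd_frac=0.03, seed=seed,
            )
            no_fa, fa, _ = simulate_lead_profiles(spec)
            fits = []
            for prof in (fa, no_fa):
                series = normalize_two_state(
                    position_series(prof, "10"), Direction.DECREASING, position="10"
                )
                fits.append(fit_two_state(series).Kd_nM)
            ddgs.append(R_KCAL_PER_K_MOL * 293.0 * np.log(fits[0] / fits[1]))
        assert np.mean(ddgs) == pytest.approx(expected, abs=0.15)
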