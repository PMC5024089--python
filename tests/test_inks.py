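"""Ink physics: power-law fits, gel points, moduli, conductivity, cooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aspireprint.fixtures import (
    gen_gelation_curve,
    gen_powerlaw_curve,
    gen_stress_strain,
)
from aspireprint.inks import (
    ConductivitySegmentSpec,
    InkSpec,
    RheologyCurve,
    StressStrain,
    find_crossover,
    fit_modulus,
    fit_power_law,
    gelation_risk,
    printability_window,
    read_rheology_curve,
    read_shear_sweep,
    read_stress_strain,
    resistance_from_conductivity,
    series_conductivity,
    specific_conductivity_from_resistance,
    switching_temperature_drop,
)


class TestPowerLaw:
    @pytest.mark.parametrize("K,n", [(100.0, 0.3), (50.0, 0.26), (1.0, 0.9), (250.0, 0.5)])
    def test_exact_recovery_from_noise_free_sweep(self, K, n):
        g, eta = gen_powerlaw_curve(K=K, n=n)
        fit = fit_power_law(g, eta)
        assert fit.n == pytest.approx(n, abs=1e-9)
        assert fit.K == pytest.approx(K, rel=1e-9)
        assert fit.residual < 1e-12

    def test_constant_viscosity_is_newtonian(self):
        g = np.logspace(-2, 2, 20)
        fit = fit_power_law(g, np.full(20, 7.5))
        assert fit.n == pytest.approx(1.0, abs=1e-12)
        assert not fit.shear_thinning

    def test_noisy_fit_recovers_index_within_tolerance(self):
        g, eta = gen_powerlaw_curve(K=100.0, n=0.3, noise_sd=0.05, seed=42)
        fit = fit_power_law(g, eta)
        assert fit.n == pytest.approx(0.3, abs=0.02)

    def test_same_seed_reproduces_sweep(self):
        a = gen_powerlaw_curve(noise_sd=0.1, seed=7)
        b = gen_powerlaw_curve(noise_sd=0.1, seed=7)
        assert np.array_equal(a[1], b[1])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0], [1.0, 2.0])  # too few
        with pytest.raises(ValueError):
            fit_power_law([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])


class TestCrossover:
    def test_constructed_gel_point_recovered(self):
        curve = gen_gelation_curve(T_x=35.0)
        assert find_crossover(curve) == pytest.approx(35.0, abs=1e-9)

    def test_log_linear_intersection_matches_closed_form(self):
        # log10 G' = 4 - 0.10 T, log10 G'' = 2 - 0.037 T -> T* = 2/0.063
        T = np.arange(20.0, 50.0, 1.0)
        gp = 10 ** (4.0 - 0.10 * T)
        gpp = 10 ** (2.0 - 0.037 * T)
        t_star = 2.0 / 0.063
        curve = RheologyCurve(tuple(T), tuple(gp), tuple(gpp))
        assert find_crossover(curve) == pytest.approx(t_star, abs=1e-9)

    def test_no_crossing_returns_none(self):
        curve = gen_gelation_curve(T_x=35.0)
        scaled = RheologyCurve(
            curve.temperature,
            tuple(g * 1e-6 for g in curve.G_storage),  # G' << G'' everywhere
            curve.G_loss,
        )
        assert find_crossover(scaled) is None

    def test_multiple_crossings_highest_temperature_wins(self):
        T = (0.0, 10.0, 20.0, 30.0)
        gp = (10.0, 0.5, 2.0, 0.5)
        gpp = (1.0, 1.0, 1.0, 1.0)
        # sign changes in each interval; the hottest is at T = 25 by symmetry
        assert find_crossover(RheologyCurve(T, gp, gpp)) == pytest.approx(25.0)


class TestModulus:
    def test_recovers_generating_modulus(self):
        curve = gen_stress_strain(E=500.4)
        assert fit_modulus(curve) == pytest.approx(500.4, abs=1e-9)

    def test_zero_stress_gives_zero_modulus(self):
        curve = StressStrain(strain=(0.0, 0.01, 0.02, 0.03), stress=(0.0,) * 4)
        assert fit_modulus(curve) == 0.0

    def test_points_beyond_window_do_not_bias_fit(self):
        linear = gen_stress_strain(E=120.0, post_linear="plateau")
        hardening = gen_stress_strain(E=120.0, post_linear="hardening")
        assert fit_modulus(linear) == pytest.approx(fit_modulus(hardening), abs=1e-12)
        assert fit_modulus(hardening) == pytest.approx(120.0, abs=1e-9)

    def test_empty_window_rejected(self):
        curve = StressStrain(strain=(0.05, 0.1, 0.15), stress=(1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            fit_modulus(curve)


class TestSeriesConductivity:
    def test_uniform_segments_reduce_to_sigma(self):
        segs = [ConductivitySegmentSpec("AC3", l, 2.5) for l in (10.0, 4.0, 10.0)]
        assert series_conductivity(segs) == pytest.approx(2.5)

    def test_two_equal_segments_harmonic_mean(self):
        segs = [
            ConductivitySegmentSpec("a", 12.0, 1.0),
            ConductivitySegmentSpec("b", 12.0, 3.0),
        ]
        assert series_conductivity(segs) == pytest.approx(1.5)

    def test_lengthening_low_sigma_middle_decreases_conductivity(self):
        """The 24 mm outer-middle-outer designs with middles 4, 8, 12 mm."""
        s_outer, s_mid = 3.0, 1.0
        values = []
        for mid in (4.0, 8.0, 12.0):
            head = (24.0 - mid) / 2
            segs = [
                ConductivitySegmentSpec("AC3", head, s_outer),
                ConductivitySegmentSpec("AC1", mid, s_mid),
                ConductivitySegmentSpec("AC3", head, s_outer),
            ]
            values.append(series_conductivity(segs))
        assert values[0] > values[1] > values[2]
        assert all(s_mid < v < s_outer for v in values)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(0.5, 20.0), st.floats(0.01, 10.0)),
        min_size=1, max_size=8,
    ))
    def test_bounded_by_min_and_max_segment_sigma(self, pairs):
        segs = [ConductivitySegmentSpec(f"i{k}", l, s) for k, (l, s) in enumerate(pairs)]
        eff = series_conductivity(segs)
        sigmas = [s.sigma for s in segs]
        assert min(sigmas) - 1e-12 <= eff <= max(sigmas) + 1e-12

    def test_interface_term_only_lowers_conductivity(self):
        segs = [
            ConductivitySegmentSpec("a", 12.0, 1.0),
            ConductivitySegmentSpec("b", 12.0, 3.0),
        ]
        assert series_conductivity(segs, interface_equiv_length=2.0) < series_conductivity(segs)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ConductivitySegmentSpec("a", 1.0, 0.0)


class TestSpecificConductivity:
    def test_closed_form(self):
        # 24 mm filament, 0.5 mm bore, 1 Mohm
        sigma = specific_conductivity_from_resistance(1e6, 24.0, 0.5)
        assert sigma == pytest.approx(0.024 / (1e6 * math.pi * 0.0005 ** 2 / 4), rel=1e-12)
        assert sigma == pytest.approx(0.1222, abs=5e-4)

    def test_sigma_scales_linearly_with_length(self):
        s1 = specific_conductivity_from_resistance(1e6, 12.0, 0.5)
        s2 = specific_conductivity_from_resistance(1e6, 24.0, 0.5)
        assert s2 == pytest.approx(2 * s1)

    def test_roundtrip_with_series_model(self):
        segs = [
            ConductivitySegmentSpec("AC3", 10.0, 3.0),
            ConductivitySegmentSpec("AC1", 4.0, 1.0),
            ConductivitySegmentSpec("AC3", 10.0, 3.0),
        ]
        eff = series_conductivity(segs)
        R = resistance_from_conductivity(eff, 24.0, 0.5)
        assert specific_conductivity_from_resistance(R, 24.0, 0.5) == pytest.approx(
            eff, rel=1e-12
        )


class TestPrintabilityWindow:
    def test_plain_agarose_window_contains_50C(self):
        inks = [InkSpec(f"A{i}", crossover_T=t) for i, t in enumerate((32.0, 38.0, 44.5))]
        lo, hi = printability_window(inks, margin=5.0, ceiling=60.0)
        assert lo <= 50.0 <= hi

    def test_bioink_window_pins_to_38C(self):
        inks = [InkSpec("AS3", crossover_T=35.0)]
        lo, hi = printability_window(inks, margin=3.0, ceiling=38.0)
        assert (lo, hi) == (38.0, 38.0)

    def test_crossover_above_ceiling_is_empty_window(self):
        with pytest.raises(ValueError, match="empty"):
            printability_window([InkSpec("X", crossover_T=59.0)], margin=5.0, ceiling=60.0)


class TestSwitchingCooldown:
    def test_limits(self):
        assert switching_temperature_drop(50.0, 25.0, 0.0, 30.0) == 50.0
        assert switching_temperature_drop(50.0, 25.0, 1e9, 30.0) == pytest.approx(25.0)

    def test_closed_form_short_excursion_stays_hot(self):
        T = switching_temperature_drop(50.0, 25.0, 3.0, 30.0)
        assert T == pytest.approx(25.0 + 25.0 * math.exp(-0.1), abs=1e-9)
        assert T == pytest.approx(47.62, abs=0.01)
        # above every plain-agarose gel point: no ink flagged
        inks = [InkSpec(f"A{i}", crossover_T=t) for i, t in enumerate((32.0, 38.0, 44.5))]
        assert gelation_risk(T, inks) == []

    def test_long_excursion_flags_gelation(self):
        T = switching_temperature_drop(50.0, 25.0, 300.0, 30.0)
        inks = [InkSpec("AS3", crossover_T=35.0)]
        assert [i.ink_id for i in gelation_risk(T, inks)] == ["AS3"]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(1.0, 600.0), st.floats(1.0, 600.0))
    def test_monotone_decreasing_in_elapsed(self, t1, t2):
        lo, hi = sorted((t1, t2))
        a = switching_temperature_drop(50.0, 25.0, lo, 30.0)
        b = switching_temperature_drop(50.0, 25.0, hi, 30.0)
        assert a >= b

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            switching_temperature_drop(50.0, 25.0, 1.0, 0.0)


class TestCsvReaders:
    def test_shear_sweep_roundtrip(self, tmp_path):
        g, eta = gen_powerlaw_curve(K=100.0, n=0.3, points=10)
        p = tmp_path / "sweep.csv"
        p.write_text("shear_rate,viscosity\n" + "\n".join(
            f"{float(a)},{float(b)}" for a, b in zip(g, eta)))
        g2, eta2 = read_shear_sweep(p)
        assert fit_power_law(g2, eta2).n == pytest.approx(0.3, abs=1e-9)

    def test_rheology_and_stress_strain_readers(self, tmp_path):
        curve = gen_gelation_curve(T_x=35.0)
        p = tmp_path / "rheo.csv"
        rows = "\n".join(
            f"{float(t)},{float(a)},{float(b)}" for t, a, b in
            zip(curve.temperature, curve.G_storage, curve.G_loss))
        p.write_text("temperature,G_storage,G_loss\n" + rows)
        assert find_crossover(read_rheology_curve(p)) == pytest.approx(35.0, abs=1e-9)

        ss = gen_stress_strain(E=500.4, points=10)
        q = tmp_path / "ss.csv"
        q.write_text("strain,stress\n" + "\n".join(
            f"{float(a)},{float(b)}" for a, b in zip(ss.strain, ss.stress)))
        assert fit_modulus(read_stress_strain(q)) == pytest.approx(500.4, abs=1e-6)
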