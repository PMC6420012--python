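"""Salvage-pathway simulator: kinetics, conservation, dataset generation."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from nadflux import (
    InputError,
    KineticParams,
    bias_scan,
    generate_dataset,
    half_life,
    induction_scenario,
    km_effective,
    parameter_recovery,
    recover_fluxes,
    simulate_labeling,
    steady_state_nad_conc,
    synthesis_flux,
)


class TestFeedbackKinetics:
    def test_km_anchors(self, default_params):
        p = default_params
        assert km_effective(0.0, p.km0, p.ki_feedback) == pytest.approx(1.0)
        assert km_effective(500.0, p.km0, p.ki_feedback) == pytest.approx(25.0)

    def test_no_feedback_limit(self):
        assert km_effective(500.0, 1.0, math.inf) == 1.0

    def test_saturation_limit(self, default_params):
        p = replace(default_params, vmax=100.0)
        assert synthesis_flux(1e9, 500.0, p) == pytest.approx(100.0, rel=1e-6)

    def test_half_max_at_km(self, default_params):
        p = replace(default_params, vmax=100.0)
        km = km_effective(500.0, p.km0, p.ki_feedback)
        assert synthesis_flux(km, 500.0, p) == pytest.approx(50.0)

    def test_closed_form_flux(self, default_params):
        # vmax 100, nam 2, km_eff(500) = 25: 100*2/27
        p = replace(default_params, vmax=100.0)
        assert synthesis_flux(2.0, 500.0, p) == pytest.approx(100.0 * 2.0 / 27.0)


class TestSimulateLabeling:
    def test_reference_run_matches_printed_numbers(self, default_params):
        """Default parameters reproduce the 3-h reference labeling state."""
        traj = simulate_labeling(default_params, [0.0, 3.0])
        d3_formed = traj.d3_nad[-1] - traj.d3_nad[0]
        d0_lost = traj.d0_nad[0] - traj.d0_nad[-1]
        assert d3_formed == pytest.approx(276.0, rel=0.05)
        assert d0_lost == pytest.approx(258.0, rel=0.05)

    def test_no_breakdown_decouples_pools(self, default_params):
        p = replace(default_params, k_b=0.0)
        traj = simulate_labeling(p, [0.0, 1.0, 2.0, 3.0])
        assert np.allclose(traj.d0_nad, traj.d0_nad[0], rtol=1e-9)
        # d3-NAD+ keeps growing at the synthesis flux, which slowly declines
        # as tracer depletes and the rising NAD+ pool tightens the feedback
        increments = np.diff(traj.d3_nad)
        assert np.all(increments > 0)
        assert increments.max() / increments.min() < 1.25

    def test_nam_moiety_conservation(self, default_params):
        traj = simulate_labeling(default_params, list(np.linspace(0.0, 9.0, 13)))
        total = traj.total_nam_moiety()
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-6

    def test_exponential_decay_oracle(self, default_params):
        """With recycling off, d0-NAD+ follows nad0*exp(-k_b t) exactly."""
        p = replace(default_params, recycling=False)
        traj = simulate_labeling(p, [0.0, 1.0, 3.0, 6.0, 9.0])
        expected = p.nad0 * p.cell_volume * np.exp(-p.k_b * traj.times)
        assert np.max(np.abs(traj.d0_nad - expected) / expected) < 1e-6

    def test_half_life_consistency(self, default_params):
        """Switching synthesis off, the pool halves at ln(2)/k_b, which is
        also flux_core.half_life evaluated at (C, k_b*C)."""
        p = replace(default_params, vmax=0.0)
        grid = list(np.linspace(0.0, 15.0, 1501))
        traj = simulate_labeling(p, grid)
        total = traj.d0_nad + traj.d3_nad
        t_half = float(np.interp(total[0] / 2.0, total[::-1], traj.times[::-1]))
        assert t_half == pytest.approx(math.log(2) / p.k_b, rel=1e-5)
        c0 = p.nad0
        assert half_life(c0, p.k_b * c0) == pytest.approx(math.log(2) / p.k_b, rel=1e-12)

    def test_steady_state_holds_total_constant(self, default_params):
        """Starting at the fixed-medium steady state, synthesis balances
        breakdown and the total pool stays flat for 9 h."""
        c_star = steady_state_nad_conc(default_params)
        p = replace(default_params, nad0=c_star, clamp_medium_nam=True)
        traj = simulate_labeling(p, [0.0, 3.0, 6.0, 9.0])
        total = traj.d0_nad + traj.d3_nad
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-7

    def test_recycled_fraction_nondecreasing(self, default_params):
        traj = simulate_labeling(default_params, [0.0, 1.0, 3.0, 6.0, 12.0, 24.0])
        nam_total = traj.d4_nam + traj.d3_nam + traj.d0_nam
        frac = (traj.d3_nam + traj.d0_nam) / nam_total
        assert np.all(np.diff(frac) >= -1e-12)

    def test_long_labeling_fails_recycling_gate(self, default_params):
        """At 3 h the simulated medium passes the 10% gate; by 24 h the
        breakdown products dominate enough to fail it."""
        from nadflux import recycling_check

        traj = simulate_labeling(default_params, [0.0, 3.0, 24.0])
        rep3 = recycling_check(traj.d3_nam[1], traj.d0_nam[1], traj.d4_nam[1])
        rep24 = recycling_check(traj.d3_nam[2], traj.d0_nam[2], traj.d4_nam[2])
        assert rep3.passed
        assert not rep24.passed

    def test_times_must_start_at_zero(self, default_params):
        with pytest.raises(InputError):
            simulate_labeling(default_params, [1.0, 2.0])

    def test_negative_parameters_rejected(self):
        with pytest.raises(InputError):
            KineticParams(vmax=-1.0)
        with pytest.raises(InputError):
            KineticParams(cell_volume=0.0)


class TestGenerateDataset:
    def test_noiseless_amounts_equal_trajectory(self, default_params):
        p = replace(default_params, noise_cv=0.0)
        peaks, meta = generate_dataset(p, [0.0, 3.0])
        traj = simulate_labeling(p, [0.0, 3.0])
        row = peaks.set_index(["time_h", "analyte"])["peak_area"]
        scale = p.cell_count / 1e6
        assert row[(3.0, "d3-NAD+")] == pytest.approx(traj.d3_nad[-1] * scale, rel=1e-12)
        assert row[(0.0, "d0-NAD+")] == pytest.approx(traj.d0_nad[0] * scale, rel=1e-12)

    def test_same_seed_is_byte_identical(self, default_params):
        a = generate_dataset(default_params, [0.0, 3.0], replicates=3)
        b = generate_dataset(default_params, [0.0, 3.0], replicates=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_different_seed_differs(self, default_params):
        a = generate_dataset(default_params, [0.0, 3.0])
        b = generate_dataset(replace(default_params, seed=1), [0.0, 3.0])
        assert not a[0]["peak_area"].equals(b[0]["peak_area"])

    def test_empirical_cv_matches_noise_model(self, default_params):
        """50 replicate observations of d3-NAD+ at 3 h show the injected CV."""
        peaks, _ = generate_dataset(default_params, [3.0], replicates=50)
        d3 = peaks[(peaks["analyte"] == "d3-NAD+")]["peak_area"].to_numpy()
        cv = d3.std(ddof=1) / d3.mean()
        assert 0.035 <= cv <= 0.065

    def test_pipeline_recovery_noiseless(self, default_params):
        """The full generate -> quantify -> estimate chain reproduces the
        trajectory's realized a/t and b/t to numerical precision."""
        p = replace(default_params, noise_cv=0.0)
        peaks, meta = generate_dataset(p, [0.0, 3.0])
        res = recover_fluxes(peaks, meta)
        traj = simulate_labeling(p, [0.0, 3.0])
        assert res.r_s == pytest.approx((traj.d3_nad[-1] - traj.d3_nad[0]) / 3.0, rel=1e-9)
        assert res.r_b == pytest.approx((traj.d0_nad[0] - traj.d0_nad[-1]) / 3.0, rel=1e-9)


class TestBiasScan:
    def test_underestimation_grows_with_time_when_recycling(self, default_params):
        scan = bias_scan(default_params, [0.5, 1.0, 2.0, 3.0, 6.0, 9.0, 12.0, 24.0])
        assert np.all(scan["bias_rs"] < 0)
        assert np.all(np.diff(scan["bias_rs"]) < 0)  # monotone worsening

    def test_bias_vanishes_toward_zero_time(self, default_params):
        scan = bias_scan(default_params, [0.01, 0.1, 1.0])
        mags = np.abs(scan["bias_rs"].to_numpy())
        assert np.all(np.diff(mags) > 0)
        assert mags[0] < 5e-4

    def test_recycling_adds_bias(self, default_params):
        times = [1.0, 3.0, 6.0, 12.0]
        on = bias_scan(default_params, times)
        off = bias_scan(replace(default_params, recycling=False), times)
        assert np.all(on["bias_rs"].to_numpy() < off["bias_rs"].to_numpy())


class TestInduction:
    def test_unit_fold_is_identity(self, default_params):
        s = induction_scenario(default_params, 1.0)
        assert s.rs_fold == pytest.approx(1.0)
        assert s.nad_fold == pytest.approx(1.0)

    def test_sixfold_vmax_is_buffered(self, default_params):
        s = induction_scenario(default_params, 6.0)
        assert 1.0 < s.rs_fold < 6.0
        assert s.rs_fold == pytest.approx(s.rb_fold)

    def test_no_feedback_saturating_nam_is_proportional(self, default_params):
        p = replace(default_params, ki_feedback=math.inf, nam_medium0=5000.0)
        s = induction_scenario(p, 6.0)
        assert s.rs_fold == pytest.approx(6.0, rel=1e-9)

    def test_steady_state_is_consistent_with_ode(self, default_params):
        """The closed-form steady state is a fixed point of the clamped ODE."""
        c_star = steady_state_nad_conc(default_params)
        p = replace(default_params, nad0=c_star, clamp_medium_nam=True)
        traj = simulate_labeling(p, [0.0, 50.0])
        total_conc = (traj.d0_nad[-1] + traj.d3_nad[-1]) / p.cell_volume
        assert total_conc == pytest.approx(c_star, rel=1e-6)


class TestParameterRecovery:
    def test_small_run_unbiased_for_rs(self, default_params):
        r = parameter_recovery(default_params, n_datasets=20, t_label=3.0)
        assert r.mean_rs == pytest.approx(r.true_rs, rel=0.05)
        assert r.n == 20
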