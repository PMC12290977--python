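import warnings

import numpy as np
import pytest

import osmotopo as ot
from osmotopo.diffusivity import PSI_AT_ZERO, _monotone_filter
from osmotopo.kinetics import KineticSeries, ShrinkageSeries

L0 = 0.00609


def brute_force_psi(tau, n_terms=200):
    """Direct 200-term summation of the diagonal cube series."""
    return (512 / np.pi**6) * sum(
        (2 * i + 1) ** -6 * np.exp(-3 * (2 * i + 1) ** 2 * np.pi**2 * tau / 4)
        for i in range(n_terms)
    )


class TestPsiModel:
    def test_value_at_zero_is_closed_form(self):
        # sum (2i+1)^-6 = pi^6/960, so psi(0) = 512/960
        assert ot.psi_model(0.0) == pytest.approx(512 / 960, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.01, 0.1, 0.5, 1.0, 2.0])
    def test_matches_brute_force_series(self, tau):
        assert ot.psi_model(tau) == pytest.approx(brute_force_psi(tau), abs=1e-13)

    def test_value_at_tenth(self):
        assert ot.psi_model(0.1) == pytest.approx(0.2540380187, abs=1e-9)

    def test_strictly_decreasing(self):
        taus = np.linspace(0, 2, 200)
        vals = np.asarray(ot.psi_model(taus))
        assert np.all(np.diff(vals) < 0)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            ot.psi_model(-0.1)


class TestInvertPsi:
    def test_boundary(self):
        assert ot.invert_psi(ot.psi_model(0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_known_round_trip(self):
        assert ot.invert_psi(0.2540380187) == pytest.approx(0.1, abs=1e-6)

    def test_round_trip_identity_over_range(self):
        rng = np.random.default_rng(7)
        for x in rng.uniform(0.0, 2.0, 100):
            assert ot.invert_psi(ot.psi_model(x)) == pytest.approx(x, abs=1e-6)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 0.6, 1.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            ot.invert_psi(bad)


class TestCharacteristicLength:
    @pytest.mark.parametrize(
        "v, expected", [(1.0, L0), (0.512, 0.8 * L0), (0.125, 0.003045)]
    )
    def test_cube_root_scaling(self, v, expected):
        assert ot.characteristic_length(v, L0) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ot.characteristic_length(0.0, L0)


class TestPsiFromKinetics:
    def test_endpoints_and_midpoint(self):
        series = KineticSeries("x", np.array([0.0, 1, 2]), np.array([0.0, 0.2, 0.4]))
        psi = ot.psi_from_kinetics(series, Ye=0.4)
        assert psi.psi[0] == pytest.approx(1.0)
        assert psi.psi[1] == pytest.approx(0.5)
        assert psi.psi[2] > 0  # clipped from exactly 0

    def test_clipping_warns(self):
        series = KineticSeries("x", np.array([0.0, 1.0]), np.array([0.0, 0.5]))
        with pytest.warns(UserWarning):
            ot.psi_from_kinetics(series, Ye=0.4)

    def test_nonpositive_ye_rejected(self):
        series = KineticSeries("x", np.array([0.0, 1.0]), np.array([0.0, 0.1]))
        with pytest.raises(ValueError):
            ot.psi_from_kinetics(series, Ye=0.0)


def synthetic_psi(config, Ye=0.436):
    kin = ot.generate_kinetics(config, Y_e=Ye, substance_label="water loss")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ot.psi_from_kinetics(kin, Ye=Ye)


class TestModifiedSlopeMethod:
    def test_recovers_d_without_shrinkage(self):
        cfg = ot.SimulationConfig(D_true=2e-10, shrink_final=1.0, seed=0)
        est = ot.modified_slope_method(
            synthetic_psi(cfg), ot.generate_shrinkage(cfg), L0=cfg.L0
        )
        assert est.D_avg == pytest.approx(2e-10, rel=0.02)
        assert est.method == "shrinkage"
        assert np.all(np.diff(est.tau_star) >= 0)

    def test_recovers_d_with_shrinkage(self):
        cfg = ot.SimulationConfig(D_true=2e-10, shrink_final=0.5, seed=0)
        est = ot.modified_slope_method(
            synthetic_psi(cfg), ot.generate_shrinkage(cfg), L0=cfg.L0
        )
        assert est.D_avg == pytest.approx(2e-10, rel=0.05)

    @pytest.mark.parametrize("d_true", [1e-10, 2e-10, 4e-10])
    @pytest.mark.parametrize("shrink_final", [1.0, 0.75, 0.5])
    def test_recovery_grid_noiseless(self, d_true, shrink_final):
        cfg = ot.SimulationConfig(D_true=d_true, shrink_final=shrink_final, seed=0)
        est = ot.modified_slope_method(
            synthetic_psi(cfg), ot.generate_shrinkage(cfg), L0=cfg.L0
        )
        assert est.D_avg == pytest.approx(d_true, rel=0.05)

    def test_noisy_replicates_median_error(self):
        errors = []
        for seed in range(20):
            cfg = ot.SimulationConfig(
                D_true=2e-10, shrink_final=0.75, kinetic_noise_frac=0.01, seed=seed
            )
            est = ot.modified_slope_method(
                synthetic_psi(cfg), ot.generate_shrinkage(cfg), L0=cfg.L0
            )
            errors.append(abs(est.D_avg / 2e-10 - 1))
        assert np.median(errors) <= 0.10

    def test_constant_psi_rejected(self):
        psi = ot.PsiSeries("x", np.arange(5.0), np.full(5, 0.4))
        shrink = ShrinkageSeries(np.array([0.0, 10.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            ot.modified_slope_method(psi, shrink, L0=L0)

    def test_too_few_usable_points_rejected(self):
        psi = ot.PsiSeries("x", np.arange(4.0), np.array([1.0, 0.9, 0.4, 0.3]))
        shrink = ShrinkageSeries(np.array([0.0, 10.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            ot.modified_slope_method(psi, shrink, L0=L0)

    def test_time_unit_invariance(self):
        """Rescaling times s -> min scales D by exactly the inverse factor."""
        cfg = ot.SimulationConfig(D_true=2e-10, shrink_final=0.75, seed=0)
        psi_s = synthetic_psi(cfg)
        shrink_s = ot.generate_shrinkage(cfg)
        est_s = ot.modified_slope_method(psi_s, shrink_s, L0=cfg.L0)
        psi_min = ot.PsiSeries(psi_s.substance, psi_s.times / 60.0, psi_s.psi)
        shrink_min = ShrinkageSeries(shrink_s.times / 60.0, shrink_s.v_ratio)
        est_min = ot.modified_slope_method(psi_min, shrink_min, L0=cfg.L0)
        assert est_min.D_avg == pytest.approx(60.0 * est_s.D_avg, rel=1e-9)

    def test_monotone_filter_drops_risers(self):
        psi = np.array([0.5, 0.4, 0.45, 0.3, 0.35, 0.2])
        keep = _monotone_filter(np.arange(6.0), psi)
        assert list(keep) == [True, True, False, True, False, True]


class TestSlopeMethodNoShrink:
    def test_exact_line_construction(self):
        d_true = 2e-10
        s = 3 * np.pi**2 * d_true / (4 * L0**2)
        t = np.linspace(0.0, 40000.0, 10)
        psi = ot.PsiSeries("x", t, (512 / np.pi**6) * np.exp(-s * t))
        est = ot.slope_method_no_shrink(psi, L0=L0)
        assert est.D_avg == pytest.approx(d_true, rel=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_late_time_series_recovery(self):
        d_true = 2e-10
        t = np.linspace(20000.0, 80000.0, 12)
        tau = d_true * t / L0**2
        psi = ot.PsiSeries("x", t, np.asarray(ot.psi_model(tau)))
        est = ot.slope_method_no_shrink(psi, L0=L0)
        assert est.D_avg == pytest.approx(d_true, rel=0.01)

    def test_uniform_scaling_leaves_d_unchanged(self):
        t = np.linspace(10000.0, 60000.0, 8)
        base = 0.4 * np.exp(-2e-5 * t)
        a = ot.slope_method_no_shrink(ot.PsiSeries("x", t, base), L0=L0)
        b = ot.slope_method_no_shrink(ot.PsiSeries("x", t, 2 * base), L0=L0)
        assert a.D_avg == pytest.approx(b.D_avg, rel=1e-12)


class TestOverestimationRatio:
    def test_identical_estimates_give_one(self):
        cfg = ot.SimulationConfig(D_true=2e-10, shrink_final=1.0, seed=1)
        psi = synthetic_psi(cfg)
        est = ot.modified_slope_method(psi, ot.generate_shrinkage(cfg), L0=cfg.L0)
        assert ot.overestimation_ratio(est, est) == pytest.approx(1.0)

    def test_no_shrinkage_data_ratio_near_one(self):
        cfg = ot.SimulationConfig(D_true=2e-10, shrink_final=1.0, seed=1)
        psi = synthetic_psi(cfg)
        shrink = ot.generate_shrinkage(cfg)
        e = ot.overestimation_ratio(
            ot.slope_method_no_shrink(psi, L0=cfg.L0),
            ot.modified_slope_method(psi, shrink, L0=cfg.L0),
        )
        assert e == pytest.approx(1.0, rel=0.03)

    @pytest.mark.parametrize("shrink_final", [0.75, 0.5])
    def test_shrinking_data_inflates_naive_estimate(self, shrink_final):
        cfg = ot.SimulationConfig(D_true=2e-10, shrink_final=shrink_final, seed=1)
        psi = synthetic_psi(cfg)
        shrink = ot.generate_shrinkage(cfg)
        e = ot.overestimation_ratio(
            ot.slope_method_no_shrink(psi, L0=cfg.L0),
            ot.modified_slope_method(psi, shrink, L0=cfg.L0),
        )
        assert e > 1.0

    def test_rejects_nonpositive(self):
        cfg = ot.SimulationConfig(seed=1)
        est = ot.modified_slope_method(
            synthetic_psi(cfg), ot.generate_shrinkage(cfg), L0=cfg.L0
        )
        bad = ot.DiffusivityEstimate(
            substance="x",
            method="no_shrinkage",
            D_avg=-1.0,
            D_stepwise=np.array([]),
            tau_star=np.array([]),
            times=np.array([]),
            L_path=np.array([]),
            r_squared=np.nan,
            rmse=np.nan,
        )
        with pytest.raises(ValueError):
            ot.overestimation_ratio(bad, est)
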