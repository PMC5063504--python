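import numpy as np
import pytest

from conftest import DOUBLE_HILL_CA, FORCE_HILL_WT, SINGLE_HILL_MG
from tncfret import (
    GaussianPeak,
    SimulationConfig,
    TitrationSeries,
    fit_double_hill,
    fit_gaussian_peak,
    fit_hill_force,
    fit_single_hill,
    force_recovery,
    ka_from_p50,
    round_sig,
    simulate_auc_distribution,
    simulate_titration,
)
from tncfret.fitting import hill_force_model, single_hill_model


def make_series(model_params, px, replicates=1, noise=0.0, seed=0, **kwargs):
    cfg = SimulationConfig(seed=seed, noise_sd=noise, mode="hill", model_params=model_params)
    return simulate_titration(cfg, px, replicates=replicates, **kwargs)


class TestForceHill:
    def test_noiseless_exact_recovery(self):
        series = make_series(FORCE_HILL_WT, np.linspace(8, 4, 12),
                             response_kind="normalized_force")
        fit = fit_hill_force(series)
        assert fit.p50 == pytest.approx(5.74, abs=1e-6)
        assert fit.n_h == pytest.approx(1.37, abs=1e-6)

    def test_midpoint_gives_half_maximal_force(self):
        assert hill_force_model(5.74, 5.74, 1.37) == pytest.approx(50.0)

    def test_limits(self):
        fit = fit_hill_force(
            make_series(FORCE_HILL_WT, np.linspace(8, 4, 12), response_kind="normalized_force")
        )
        assert hill_force_model(-20.0, fit.p50, fit.n_h) == pytest.approx(100.0, abs=1e-6)
        assert hill_force_model(20.0, fit.p50, fit.n_h) == pytest.approx(0.0, abs=1e-6)

    def test_rising_force_with_pca_rejected(self):
        px = np.linspace(8, 4, 12)
        series = TitrationSeries(
            ion="Ca", pX=px, response=100.0 - hill_force_model(px, 5.74, 1.37),
            response_kind="normalized_force",
        )
        with pytest.raises(ValueError, match="increases with pCa"):
            fit_hill_force(series)

    def test_wrong_response_kind_rejected(self):
        series = make_series(FORCE_HILL_WT, np.linspace(8, 4, 12))
        with pytest.raises(ValueError, match="normalized_force"):
            fit_hill_force(series)


class TestSingleHill:
    def test_noiseless_exact_recovery_of_mg_titration(self):
        series = make_series(SINGLE_HILL_MG, np.linspace(5.5, 1.5, 15), ion="Mg")
        fit = fit_single_hill(series)
        assert fit.p50 == pytest.approx(3.28, rel=1e-4)
        assert fit.n_h == pytest.approx(1.09, rel=1e-4)
        assert fit.f_min == pytest.approx(0.043, rel=1e-4)
        assert fit.f_max == pytest.approx(0.215, rel=1e-4)

    def test_constant_offset_shifts_only_f_min(self):
        px = np.linspace(5.5, 1.5, 15)
        base = make_series(SINGLE_HILL_MG, px, ion="Mg")
        shifted = TitrationSeries(ion="Mg", pX=px, response=base.response + 0.5)
        f0, f1 = fit_single_hill(base), fit_single_hill(shifted)
        assert f1.f_min - f0.f_min == pytest.approx(0.5, abs=1e-6)
        assert f1.p50 == pytest.approx(f0.p50, abs=1e-6)
        assert f1.n_h == pytest.approx(f0.n_h, abs=1e-6)
        assert f1.f_max == pytest.approx(f0.f_max, abs=1e-6)

    def test_too_few_points_rejected(self):
        series = make_series(SINGLE_HILL_MG, np.linspace(5, 2, 5), ion="Mg")
        with pytest.raises(ValueError, match="distinct"):
            fit_single_hill(series)

    def test_flat_data_rejected(self):
        px = np.linspace(5.5, 1.5, 12)
        series = make_series(
            dict(f_min=0.1, f_max=0.0, n=1.0, p50=3.0), px,
            replicates=4, noise=0.01, seed=3, ion="Mg",
        )
        with pytest.raises(ValueError, match="no transition"):
            fit_single_hill(series)

    def test_se_shrinks_with_replicates(self):
        px = np.linspace(5.5, 1.5, 15)
        ses = []
        for reps in (2, 16):
            series = make_series(SINGLE_HILL_MG, px, replicates=reps, noise=0.005, seed=5, ion="Mg")
            ses.append(fit_single_hill(series).se["p50"])
        assert ses[1] < ses[0]


class TestDoubleHill:
    def test_noiseless_exact_recovery_of_biphasic_titration(self):
        series = make_series(DOUBLE_HILL_CA, np.linspace(9.5, 4.0, 25))
        fit = fit_double_hill(series)
        for name, expected in [
            ("f_min", 0.040), ("f_max1", 0.133), ("n1", 2.70), ("p50_1", 7.17),
            ("f_max2", -0.082), ("n2", 0.94), ("p50_2", 5.47),
        ]:
            assert getattr(fit, name) == pytest.approx(expected, rel=1e-4), name

    def test_component_ordering_by_affinity(self):
        series = make_series(DOUBLE_HILL_CA, np.linspace(9.5, 4.0, 25))
        fit = fit_double_hill(series)
        assert fit.p50_1 > fit.p50_2

    def test_reduces_to_single_hill_when_one_component_absent(self):
        px = np.linspace(5.5, 1.5, 20)
        series = make_series(SINGLE_HILL_MG, px, ion="Mg")
        double = fit_double_hill(series)
        single = fit_single_hill(series)
        dominant = max(
            [(double.f_max1, double.p50_1), (double.f_max2, double.p50_2)],
            key=lambda c: abs(c[0]),
        )
        assert dominant[1] == pytest.approx(single.p50, abs=0.01)
        assert min(abs(double.f_max1), abs(double.f_max2)) < 0.05 * abs(single.f_max)

    def test_too_few_points_rejected(self):
        series = make_series(DOUBLE_HILL_CA, np.linspace(9.5, 4.0, 9))
        with pytest.raises(ValueError, match="distinct"):
            fit_double_hill(series)

    def test_collapsed_midpoints_flagged(self):
        """Two near-coincident same-sign components look like one
        transition; the fit must raise a weak-identification flag (either
        collapsed midpoints or an amplitude indistinguishable from zero)."""
        params = dict(f_min=0.04, f_max1=0.1, n1=1.0, p50_1=5.55,
                      f_max2=0.1, n2=1.0, p50_2=5.45)
        series = make_series(params, np.linspace(9.5, 4.0, 25))
        fit = fit_double_hill(series)
        assert fit.flags


class TestGaussianPeak:
    def test_noiseless_exact_recovery(self):
        s, f = simulate_auc_distribution(
            [GaussianPeak(1.0, 4.18, 0.12)], np.arange(3.0, 5.5 + 0.005, 0.01)
        )
        fit = fit_gaussian_peak(s, f)
        assert fit.s_mean == pytest.approx(4.18, abs=1e-6)
        assert fit.delta == pytest.approx(0.12, abs=1e-6)
        assert fit.a0 == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_data_peak_at_argmax(self, rng):
        s, f = simulate_auc_distribution(
            [GaussianPeak(1.0, 4.2, 0.15)], np.arange(3.0, 5.5, 0.01),
            noise_sd=0.002, seed=rng,
        )
        fit = fit_gaussian_peak(s, f)
        assert abs(fit.s_mean - s[np.argmax(f)]) < 0.01 + 1e-9

    def test_window_isolates_one_peak_of_a_mixture(self):
        """Ca-saturated and apo species sediment separately; a window
        around the compact (4.45 S) peak recovers its mean."""
        s, f = simulate_auc_distribution(
            [GaussianPeak(0.9, 4.18, 0.10), GaussianPeak(1.0, 4.45, 0.05)],
            np.arange(3.0, 5.5, 0.005),
        )
        fit = fit_gaussian_peak(s, f, window=(4.35, 4.6))
        assert fit.s_mean == pytest.approx(4.45, abs=0.02)

    def test_window_without_maximum_rejected(self):
        s, f = simulate_auc_distribution(
            [GaussianPeak(1.0, 4.18, 0.12)], np.arange(3.0, 5.5, 0.01)
        )
        with pytest.raises(ValueError, match="local maximum"):
            fit_gaussian_peak(s, f, window=(5.0, 5.5))


class TestKaConversion:
    def test_strictly_increasing(self):
        p = np.linspace(0, 10, 30)
        ka = [ka_from_p50(x) for x in p]
        assert all(a < b for a, b in zip(ka, ka[1:]))

    def test_unit_consistency_with_px(self):
        """K_a(pX(free)) * free = 1: the midpoint affinity is the
        reciprocal of the free concentration at half saturation."""
        from tncfret import pX

        free = 3.7e-6
        assert ka_from_p50(pX(free)) * free == pytest.approx(1.0, rel=1e-12)

    def test_identity_at_zero(self):
        assert ka_from_p50(0.0) == 1.0

    @pytest.mark.parametrize("x,expected", [(1490.0, 1500.0), (0.0, 0.0), (-0.0821, -0.082)])
    def test_round_sig(self, x, expected):
        assert round_sig(x) == expected


class TestForceRecovery:
    def test_thresholds_are_strict(self):
        r = force_recovery(100.0, 20.0, 70.0)
        assert r.extraction_residual_pct == 20.0 and not r.extraction_ok
        assert r.recovery_pct == 70.0 and r.recovery_ok

    def test_satisfactory_preparation(self):
        r = force_recovery(100.0, 15.0, 70.0)
        assert r.extraction_ok and r.recovery_ok

    def test_complete_extraction_and_recovery(self):
        r = force_recovery(100.0, 0.0, 100.0)
        assert r.extraction_residual_pct == 0.0
        assert r.recovery_pct == 100.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            force_recovery(0.0, 1.0, 1.0)


def test_multi_start_invariance():
    """All documented start points converge to the same optimum on
    noiseless single-Hill data (checked via the best-fit residual being
    essentially zero, which any start must reach for the test above to
    recover exactly)."""
    px = np.linspace(5.5, 1.5, 15)
    curve = single_hill_model(px, **{k: SINGLE_HILL_MG[k] for k in ("f_min", "f_max", "n", "p50")})
    series = TitrationSeries(ion="Mg", pX=px, response=curve)
    fit = fit_single_hill(series)
    assert fit.residual_ss < 1e-12
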