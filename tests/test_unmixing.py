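import copy

import numpy as np
import pytest

from tncfret import (
    DEFAULT_CA_CONTRIBUTIONS,
    KNOCKOUT_PANEL,
    SimulationConfig,
    Spectrum,
    analyze_endpoint,
    correct_direct,
    direct_excitation_fraction,
    fret_ratio,
    peak_read,
    simulate_acceptor_only,
    simulate_endpoint_experiment,
    simulate_spectrum,
    unmix,
    unmix_scan,
)
from tncfret.unmixing import UnmixResult


def normal_equations(spectrum, refs):
    """Independent 2-variable closed-form least-squares oracle."""
    d, a, y = refs.donor_emission, refs.acceptor_emission, spectrum.intensity
    g11, g12, g22 = d @ d, d @ a, a @ a
    b1, b2 = d @ y, a @ y
    det = g11 * g22 - g12 * g12
    return ((g22 * b1 - g12 * b2) / det, (g11 * b2 - g12 * b1) / det)


class TestUnmix:
    def test_pure_donor_recovered_exactly(self, refs):
        sp = simulate_spectrum(0.0, 2.0, 433, refs)
        amp = unmix(sp, refs)
        assert amp.f_don == pytest.approx(2.0, abs=1e-12)
        assert amp.f_acc == pytest.approx(0.0, abs=1e-12)
        assert amp.residual_ss == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_and_grid_search(self, refs, rng):
        """lstsq solution equals the closed form and a fine grid search."""
        truth = (1.5, 0.8)
        y = 1.5 * refs.donor_emission + 0.8 * refs.acceptor_emission
        y = y + rng.normal(0, 0.01, y.size)
        sp = Spectrum(refs.wavelength_nm, y, excitation_nm=433)
        amp = unmix(sp, refs)

        ne = normal_equations(sp, refs)
        assert amp.f_don == pytest.approx(ne[0], abs=1e-10)
        assert amp.f_acc == pytest.approx(ne[1], abs=1e-10)

        # brute-force grid search at 1e-4 resolution around the truth
        fd = np.arange(truth[0] - 0.02, truth[0] + 0.02, 1e-4)
        fa = np.arange(truth[1] - 0.02, truth[1] + 0.02, 1e-4)
        fits = (
            np.sum(
                (
                    y[None, None, :]
                    - fd[:, None, None] * refs.donor_emission
                    - fa[None, :, None] * refs.acceptor_emission
                )
                ** 2,
                axis=2,
            )
        )
        i, j = np.unravel_index(np.argmin(fits), fits.shape)
        assert amp.f_don == pytest.approx(fd[i], abs=1e-4)
        assert amp.f_acc == pytest.approx(fa[j], abs=1e-4)
        # and the noisy recovery is close to the generating amplitudes
        se = 0.01 / np.sqrt(len(y))
        assert amp.f_don == pytest.approx(truth[0], abs=3 * se * 10)
        assert amp.f_acc == pytest.approx(truth[1], abs=3 * se * 10)

    def test_negative_amplitude_flagged_not_clipped(self, refs):
        y = 1.0 * refs.donor_emission - 0.05 * refs.acceptor_emission
        sp = Spectrum(refs.wavelength_nm, y, excitation_nm=433)
        with pytest.warns(UserWarning, match="negative"):
            amp = unmix(sp, refs)
        assert amp.negative
        assert amp.f_acc == pytest.approx(-0.05, abs=1e-10)

    def test_grid_extrapolation_refused(self, refs):
        sp = Spectrum(np.arange(300.0, 700.0), np.ones(400), excitation_nm=433)
        with pytest.raises(ValueError, match="extrapolation"):
            unmix(sp, refs)


class TestDirectExcitationCorrection:
    def test_identical_controls_give_unity(self, refs):
        c = simulate_acceptor_only(515.0, 50.0, refs)
        assert direct_excitation_fraction(c, c, refs) == pytest.approx(1.0)

    def test_recovers_generator_profile(self, refs):
        c433 = simulate_acceptor_only(433.0, 50.0, refs)
        c515 = simulate_acceptor_only(515.0, 50.0, refs)
        r = direct_excitation_fraction(c433, c515, refs)
        assert r == pytest.approx(refs.direct_profile(433.0), abs=1e-10)

    def test_ratio_decreases_down_the_excitation_ladder(self, refs):
        c515 = simulate_acceptor_only(515.0, 50.0, refs)
        ladder = [433, 424, 420, 418, 414, 410, 408, 404, 400]
        ratios = [
            direct_excitation_fraction(simulate_acceptor_only(ex, 50.0, refs), c515, refs)
            for ex in ladder
        ]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))
        assert all(0 <= r <= 1 for r in ratios)

    def test_unusable_control_rejected(self, refs):
        good = simulate_acceptor_only(515.0, 50.0, refs)
        bad = Spectrum(refs.wavelength_nm, -refs.acceptor_emission, excitation_nm=515)
        with pytest.raises(ValueError, match="unusable"):
            direct_excitation_fraction(good, bad, refs)

    def test_correct_direct_identities(self):
        assert correct_direct(5.0, 10.0, 0.0) == 5.0
        assert correct_direct(2.0, 20.0, 0.1) == pytest.approx(0.0)

    def test_correct_direct_recovers_known_fret(self, refs, rng):
        """Generator scan with F_AccFRET = 12.0 is recovered through the
        full unmix + direct-excitation correction."""
        direct515 = 8.0
        r_true = refs.direct_profile(433.0)
        sp = simulate_spectrum(
            0.12, 100.0, 433, refs,
            acceptor_direct_amount=direct515 * r_true, noise_sd=0.05, seed=rng,
        )
        amp = unmix(sp, refs)
        f_acc_fret = correct_direct(amp.f_acc, direct515, r_true)
        se = 0.05 / np.sqrt(len(sp)) * 10
        assert f_acc_fret == pytest.approx(12.0, abs=3 * se)


class TestFretRatio:
    def test_zero_fret_gives_zero_ratio(self):
        assert fret_ratio(0.0, 10.0) == 0.0

    def test_nonpositive_donor_rejected(self):
        with pytest.raises(ValueError, match="uninterpretable"):
            fret_ratio(1.0, 0.0)

    def test_noiseless_round_trip_at_printed_wt_value(self, refs):
        """Full pipeline (unmix -> control ratio -> correction -> ratio)
        returns the generating F_R = 0.217 to 1e-9 with a direct-excitation
        component present."""
        direct515 = 10.0
        ex = 424.0
        sp = simulate_spectrum(
            0.217, 80.0, ex, refs, acceptor_direct_amount=direct515 * refs.direct_profile(ex)
        )
        c_ex = simulate_acceptor_only(ex, direct515, refs)
        c_max = simulate_acceptor_only(515.0, direct515, refs)
        r = direct_excitation_fraction(c_ex, c_max, refs)
        amp = unmix(sp, refs)
        f_r = fret_ratio(correct_direct(amp.f_acc, direct515, r), amp.f_don)
        assert f_r == pytest.approx(0.217, abs=1e-9)

    def test_invariant_across_excitation_ladder(self):
        """F_R does not depend on lambda_ex: SD across the 9-wavelength
        ladder stays under 2% of the mean at 0.5% intensity noise."""
        cfg = SimulationConfig(seed=42, noise_sd=0.5)  # 0.5% of donor amplitude 100
        ds = simulate_endpoint_experiment(
            KNOCKOUT_PANEL["CTV-TnC WT"], DEFAULT_CA_CONTRIBUTIONS, "Ca-in-EDTA", cfg
        )
        result = analyze_endpoint(ds)
        ca_cond = ds.condition_order[1]
        frs = np.array([s.f_r for s in result.per_scan if s.condition == ca_cond])
        assert frs.size == 9
        assert np.std(frs, ddof=1) < 0.02 * np.mean(frs)


class TestUnmixResultConservation:
    def test_acceptor_amplitude_conserved_exactly(self, refs, rng):
        """F_Acc = F_AccFRET + F_AccDirect holds identically, by construction."""
        sp = simulate_spectrum(0.3, 50.0, 433, refs, acceptor_direct_amount=1.0,
                               noise_sd=0.1, seed=rng)
        res = unmix_scan(sp, refs, sample_acc_at_direct_max=10.0, r=0.1)
        assert res.f_acc_fret + res.f_acc_direct == res.f_acc
        assert isinstance(res, UnmixResult)


class TestAnalyzeEndpoint:
    @pytest.fixture()
    def wt_dataset(self):
        cfg = SimulationConfig(seed=8, noise_sd=0.2)
        return simulate_endpoint_experiment(
            KNOCKOUT_PANEL["CTV-TnC WT"], DEFAULT_CA_CONTRIBUTIONS, "Ca-in-EDTA", cfg
        )

    def test_identical_conditions_give_zero_signal(self, wt_dataset):
        ds = copy.deepcopy(wt_dataset)
        first = ds.condition_order[0]
        for cond in ds.condition_order[1:]:
            ds.scans[cond] = ds.scans[first]
            ds.sample_direct_scans[cond] = ds.sample_direct_scans[first]
        result = analyze_endpoint(ds)
        assert result.delta_fr == 0.0
        assert result.reversibility_gap == 0.0

    def test_recovers_wt_signal(self, wt_dataset):
        result = analyze_endpoint(wt_dataset)
        assert result.delta_fr == pytest.approx(0.204, abs=0.01)
        assert result.reversible

    def test_missing_condition_rejected(self, wt_dataset):
        ds = copy.deepcopy(wt_dataset)
        del ds.scans[ds.condition_order[2]]
        with pytest.raises(ValueError, match="missing condition"):
            analyze_endpoint(ds)

    def test_missing_control_excludes_excitation(self, wt_dataset):
        ds = copy.deepcopy(wt_dataset)
        del ds.control_scans[400.0]
        with pytest.warns(UserWarning, match="excluded"):
            result = analyze_endpoint(ds)
        assert result.excluded_excitations == [400.0]
        n_conditions = 3
        assert len(result.per_scan) == 8 * n_conditions

    def test_nonreversible_dataset_flagged(self, wt_dataset):
        """A final condition shifted well beyond noise must raise the
        reversibility flag."""
        cfg = SimulationConfig(seed=99, noise_sd=0.2, resting_fr=0.40)
        shifted = simulate_endpoint_experiment(
            KNOCKOUT_PANEL["CTV-TnC WT"], DEFAULT_CA_CONTRIBUTIONS, "Ca-in-EDTA", cfg
        )
        ds = copy.deepcopy(wt_dataset)
        last = ds.condition_order[2]
        ds.scans[last] = shifted.scans[shifted.condition_order[2]]
        ds.sample_direct_scans[last] = shifted.sample_direct_scans[shifted.condition_order[2]]
        result = analyze_endpoint(ds)
        assert not result.reversible
        assert result.reversibility_gap > 5 * result.reversibility_gap_se


class TestPeakRead:
    def test_flat_spectrum_reads_unity(self, refs):
        sp = Spectrum(refs.wavelength_nm, np.ones(refs.wavelength_nm.size), excitation_nm=433)
        assert peak_read(sp) == (1.0, 1.0)

    def test_pure_donor_crosstalk_at_acceptor_read(self, refs):
        """Peak reads on a donor-only scan report donor bleed at 515 nm —
        the cross-talk that motivates unmixing as the default."""
        sp = simulate_spectrum(0.0, 1.0, 433, refs)
        f_don, f_acc = peak_read(sp)
        i515 = np.argmin(np.abs(refs.wavelength_nm - 515.0))
        assert f_acc == refs.donor_emission[i515]
        assert f_acc > 0
        assert f_don == 1.0

    def test_tie_resolves_to_lower_wavelength(self):
        grid = np.array([474.5, 475.5, 514.5, 515.5, 600.0])
        sp = Spectrum(grid, np.arange(5.0), excitation_nm=433)
        assert peak_read(sp) == (0.0, 2.0)

    def test_read_outside_window_rejected(self, refs):
        sp = simulate_spectrum(0.0, 1.0, 433, refs)
        with pytest.raises(ValueError, match="outside"):
            peak_read(sp, donor_peak_nm=300.0)
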