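"""Master-loading PCA, sine fitting, confidence intervals, aspect ratios."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fiberalign import pca_alignment as pa
from fiberalign import preprocess, synthetic
from fiberalign.pca_alignment import AlignmentError
from fiberalign.raman_io import AcquisitionMeta, Spectrum, SpectrumSet

GRID = np.arange(1400.0, 1801.0)


def _set_from_matrix(X):
    return SpectrumSet([
        Spectrum(GRID, row, AcquisitionMeta("s", "MC", 1, i + 1, 1, 0.0))
        for i, row in enumerate(X)])


class TestDeriveLoading:
    def test_amide_band_variation_concentrates_loading(self):
        # spectra differing only in amide-I band height: the loading is the
        # normalized band shape, supported in 1630-1700 and positive at 1665
        rng = np.random.default_rng(0)
        band = np.exp(-0.5 * ((GRID - 1665.0) / 12.0) ** 2)
        background = 50.0 + 0.01 * (GRID - 1400.0)
        X = np.array([background + h * band
                      for h in 100 + 30 * rng.standard_normal(40)])
        loading = pa.derive_loading(_set_from_matrix(X))
        window = (GRID >= 1630.0) & (GRID <= 1700.0)
        assert np.sum(loading.coefficients[window] ** 2) >= 0.95
        assert loading.coefficients[np.argmin(np.abs(GRID - 1665.0))] > 0

    def test_single_point_variation_gives_indicator_loading(self):
        X = np.tile(np.linspace(1, 2, GRID.size), (2, 1))
        X[1, 100] += 1.0
        loading = pa.derive_loading(_set_from_matrix(X))
        e = np.zeros(GRID.size)
        e[100] = 1.0
        assert min(np.linalg.norm(loading.coefficients - e),
                   np.linalg.norm(loading.coefficients + e)) < 1e-9

    def test_degenerate_sets_rejected(self):
        X = np.tile(np.linspace(1, 2, GRID.size), (110, 1))
        with pytest.raises(AlignmentError, match="identical"):
            pa.derive_loading(_set_from_matrix(X))
        with pytest.raises(AlignmentError, match="2 reference"):
            pa.derive_loading(_set_from_matrix(X[:1]))

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(1)
        band = np.exp(-0.5 * ((GRID - 1665.0) / 12.0) ** 2)
        X = np.array([100 + h * band for h in rng.random(20)])
        l1 = pa.derive_loading(_set_from_matrix(X))
        l2 = pa.derive_loading(_set_from_matrix(X[::-1].copy()))
        assert np.allclose(l1.coefficients, l2.coefficients, atol=1e-9)


class TestProjection:
    @pytest.fixture()
    def loading(self):
        rng = np.random.default_rng(2)
        X = 100 + rng.random((30, GRID.size))
        return pa.derive_loading(_set_from_matrix(X))

    def test_reference_mean_scores_zero(self, loading):
        s = _set_from_matrix(loading.reference_mean[None, :])
        assert abs(pa.project_pc1(s, loading)[0][1]) < 1e-9

    def test_projection_identity_and_linearity(self, loading):
        c = 2.75
        s = _set_from_matrix(
            (loading.reference_mean + c * loading.coefficients)[None, :])
        assert abs(pa.project_pc1(s, loading)[0][1] - c) < 1e-9
        rng = np.random.default_rng(3)
        s1, s2 = rng.random((2, GRID.size))
        scores = pa.project_pc1(_set_from_matrix(
            np.vstack([s1, s2, s1 + s2 - loading.reference_mean])), loading)
        vals = [v for _, v in scores]
        assert abs(vals[2] - (vals[0] + vals[1])) < 1e-9

    def test_grid_mismatch_is_hard_error(self, loading):
        other = Spectrum(GRID[:-1], np.ones(GRID.size - 1),
                         AcquisitionMeta("s", "MC", 1, 1, 1, 0.0))
        with pytest.raises(AlignmentError, match="resample"):
            pa.project_pc1(SpectrumSet([other]), loading)


class TestVarianceExplained:
    def test_single_direction_takes_all_variance(self):
        direction = np.sin(GRID / 40.0)
        X = np.array([100 + t * direction for t in np.linspace(0, 1, 12)])
        fracs = pa.variance_explained(_set_from_matrix(X))
        assert fracs[0] > 1 - 1e-9

    def test_isotropic_noise_spreads_evenly(self):
        rng = np.random.default_rng(4)
        d = 5
        X = np.zeros((4000, GRID.size))
        X[:, :d] = rng.standard_normal((4000, d))
        fracs = pa.variance_explained(_set_from_matrix(X))
        assert np.all(np.abs(fracs[:d] - 1.0 / d) < 0.2 / d)

    def test_fractions_normalized_and_sorted(self):
        rng = np.random.default_rng(5)
        fracs = pa.variance_explained(
            _set_from_matrix(rng.random((20, GRID.size))))
        assert abs(np.sum(fracs) - 1.0) < 1e-9
        assert np.all(np.diff(fracs) <= 1e-12)


class TestSineFit:
    @staticmethod
    def _scores(offset, A, phase, angles=(0, 30, 60, 90, 120, 150)):
        return {phi: offset + A * np.sin(np.pi * (phi - phase) / 90.0)
                for phi in angles}

    def test_noiseless_parameters_recovered(self):
        fit = pa.fit_sine(self._scores(0.2, 0.5, 30.0))
        assert abs(fit.pc1_offset - 0.2) < 1e-6
        assert abs(fit.amplitude - 0.5) < 1e-6
        assert abs(fit.phase_deg - 30.0) < 1e-6
        assert fit.aligned

    @pytest.mark.parametrize("phase,beta", [(75.0, 120.0), (45.0, 90.0),
                                            (150.0, 15.0)])
    def test_phase_to_alignment_angle(self, phase, beta):
        fit = pa.fit_sine(self._scores(0.0, 1.0, phase))
        assert abs(pa.alignment_angle(fit) - beta) < 1e-6

    def test_constant_scores_flagged_unaligned(self):
        fit = pa.fit_sine({phi: [1.3] for phi in (0, 30, 60, 90, 120, 150)})
        assert fit.amplitude < 1e-9 and not fit.aligned
        with pytest.raises(AlignmentError, match="unaligned"):
            pa.alignment_angle(fit)

    def test_too_few_angles_rejected(self):
        with pytest.raises(AlignmentError, match="3 distinct"):
            pa.fit_sine({0.0: [1.0], 90.0: [2.0]})

    @given(phase=st.floats(0.0, 179.9), amp=st.floats(0.05, 5.0),
           offset=st.floats(-2.0, 2.0))
    def test_recovery_property(self, phase, amp, offset):
        fit = pa.fit_sine(self._scores(offset, amp, phase))
        assert abs(fit.amplitude - amp) < 1e-6
        d = abs(fit.phase_deg - phase) % 180.0
        assert min(d, 180.0 - d) < 1e-5


class TestConfidenceInterval:
    @pytest.mark.parametrize("mean,sd,lo,hi", [
        (0.83, 0.05, 0.81, 0.85),
        (0.37, 0.06, 0.34, 0.40),
        (0.40, 0.07, 0.37, 0.43),
    ])
    def test_printed_intervals_from_mean_sd_n22(self, mean, sd, lo, hi):
        rng = np.random.default_rng(7)
        v = rng.standard_normal(22)
        v = (v - v.mean()) / v.std(ddof=1) * sd + mean
        got = pa.confidence_interval(v)
        assert round(got[0], 2) == lo and round(got[1], 2) == hi

    def test_degenerate_and_invalid(self):
        lo, hi = pa.confidence_interval([2.0, 2.0, 2.0])
        assert lo == hi == 2.0
        with pytest.raises(AlignmentError):
            pa.confidence_interval([1.0])


class TestAspectRatio:
    def test_printed_amplitudes_give_printed_gammas(self):
        g = pa.aspect_ratio({"CE": 0.83, "ME": 0.37, "MC": 0.40})
        assert round(g["CE"], 2) == 1.00
        assert round(g["ME"], 2) == 0.45
        assert round(g["MC"], 2) == 0.48

    def test_single_and_equal_locations(self):
        assert pa.aspect_ratio({"CE": 0.5}) == {"CE": 1.0}
        assert set(pa.aspect_ratio({"a": 2.0, "b": 2.0}).values()) == {1.0}

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(AlignmentError):
            pa.aspect_ratio({"CE": 0.0, "ME": 0.4})


class TestEndToEndRecovery:
    def test_phase_and_amplitude_recovery_through_pipeline(
            self, reference_loading):
        """Generator phase is recovered within 5 degrees at SNR >= 10 and
        the fitted amplitude increases with modulation depth."""
        cfg = preprocess.PreprocessConfig(average_replicates=False)
        amps = []
        for m in (0.1, 0.3, 0.5, 0.8):
            model = synthetic.SpectrumModel(
                bands=synthetic._default_bands(m), phase_deg=130.0,
                noise_sd=10.0, seed=11)
            sset = synthetic.gen_polarized_spectra(model, replicates=3)
            scores = pa.project_pc1(preprocess.preprocess(sset, cfg),
                                    reference_loading)
            by_angle = {}
            for meta, s in scores:
                by_angle.setdefault(meta.pol_angle_deg, []).append(s)
            fit = pa.fit_sine(by_angle)
            amps.append(fit.amplitude)
            if m >= 0.3:  # SNR >= 10 regime
                d = abs(fit.phase_deg - 130.0) % 180.0
                assert min(d, 180.0 - d) < 5.0
        assert np.all(np.diff(amps) > 0)
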