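"""PM basis fitting, scores, rVAR, accelerations, spectra, robustness."""

import numpy as np
import pandas as pd
import pytest

import pmgait
from pmgait.decomposition import _fix_signs
from pmgait.errors import DegenerateInputError, ValidationError
from pmgait.posture import PostureMatrix, pool


def _posture(values, subject="S01", condition="100", layout=None):
    layout = layout or tuple(f"M{i}" for i in range(values.shape[1] // 3))
    return PostureMatrix(values=np.asarray(values, dtype=float),
                         subject_id=subject, condition=condition,
                         fs_hz=150.0, layout=layout)


class TestFitBasis:
    def test_matches_svd_oracle(self, rng):
        # independent route: SVD of the centered data matrix
        x = rng.normal(size=(200, 6))
        basis = pmgait.fit_basis(x)
        xc = x - x.mean(axis=0)
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
        eig_oracle = s**2 / (x.shape[0] - 1)
        vec_oracle = _fix_signs(vt.T)
        np.testing.assert_allclose(basis.eigenvalues, eig_oracle, atol=1e-8)
        np.testing.assert_allclose(basis.eigenvectors, vec_oracle, atol=1e-8)

    def test_one_dimensional_data(self, rng):
        x = np.zeros((50, 6))
        x[:, 2] = rng.normal(size=50)
        basis = pmgait.fit_basis(x)
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0)
        assert abs(basis.eigenvectors[2, 0]) == pytest.approx(1.0)

    def test_planted_two_mode_variance_ratio(self, rng):
        # two orthogonal planted modes with 9:1 variance, no noise
        d = 6
        u1 = np.zeros(d); u1[0] = 1.0
        u2 = np.zeros(d); u2[3] = 1.0
        t = rng.normal(size=(2000, 2)) * np.array([3.0, 1.0])
        x = np.outer(t[:, 0], u1) + np.outer(t[:, 1], u2)
        shares = 100 * pmgait.fit_basis(x).explained_variance_ratio
        assert shares[0] == pytest.approx(90.0, abs=1.0)
        assert shares[1] == pytest.approx(10.0, abs=1.0)

    def test_orthonormal_columns_and_variance_conservation(self, basis, pooled):
        v = basis.eigenvectors
        gram = v.T @ v
        assert np.abs(gram - np.eye(v.shape[1])).max() < 1e-8
        total = pooled.values.var(axis=0, ddof=1).sum()
        assert basis.eigenvalues.sum() == pytest.approx(total, rel=1e-8)

    def test_sign_convention_stable_across_refits(self, pooled):
        a = pmgait.fit_basis(pooled)
        b = pmgait.fit_basis(pooled)
        np.testing.assert_array_equal(a.eigenvectors, b.eigenvectors)

    def test_too_few_rows(self):
        with pytest.raises(ValidationError):
            pmgait.fit_basis(np.ones((1, 4)))


class TestProjection:
    def test_score_variances_equal_eigenvalues(self, basis, pooled):
        pp = pooled.values @ basis.eigenvectors
        np.testing.assert_allclose(pp.var(axis=0, ddof=1),
                                   basis.eigenvalues, atol=1e-8)
        cov = np.cov(pp, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * basis.eigenvalues[0]

    def test_full_reconstruction(self, basis, pooled):
        trial = pooled.trials[0]
        scores = pmgait.project(basis, trial)
        rec = pmgait.reconstruct(basis, scores)
        assert np.abs(rec - trial.values).max() < 1e-8

    def test_distances_preserved(self, basis, pooled, rng):
        x = pooled.trials[0].values
        pp = x @ basis.eigenvectors
        i, j = rng.integers(0, x.shape[0], size=2)
        assert np.linalg.norm(x[i] - x[j]) == pytest.approx(
            np.linalg.norm(pp[i] - pp[j]), abs=1e-9)

    def test_dimension_mismatch(self, basis):
        bad = _posture(np.random.default_rng(0).normal(size=(10, 6)))
        with pytest.raises(ValidationError, match="mismatch"):
            pmgait.project(basis, bad)


class TestRvar:
    def test_shares_sum_to_100_over_all_components(self, scores):
        full = pmgait.participant_rvar(scores, k_retained=10**6)
        sums = full.groupby(["subject", "condition"])["value"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 100.0, atol=1e-6)

    def test_planted_two_mode_subject(self, rng):
        d = 6
        t = rng.normal(size=(3000, 2)) * np.array([3.0, 1.0])
        x = np.zeros((3000, d))
        x[:, 0], x[:, 3] = t[:, 0], t[:, 1]
        pm = _posture(x)
        basis = pmgait.fit_basis(x)
        sc = pmgait.project(basis, pm)
        out = pmgait.participant_rvar([sc], k_retained=2)
        vals = out.sort_values("pm")["value"].to_numpy()
        assert vals[0] == pytest.approx(90.0, abs=1.0)
        assert vals[1] == pytest.approx(10.0, abs=1.0)

    def test_subject_scope_pools_conditions(self, scores):
        out = pmgait.participant_rvar(scores, scope="subject")
        assert set(out["condition"]) == {"pooled"}
        assert len(out) == len({s.subject_id for s in scores}) * 5

    def test_pa_rvar_uses_acceleration_series(self, scores):
        pa = pmgait.participant_rvar(scores, use_pa=True)
        pp = pmgait.participant_rvar(scores)
        assert set(pa["metric"]) == {"pa_rvar"}
        # acceleration reweights toward high-frequency PMs: profiles differ
        assert not np.allclose(pa["value"].to_numpy(), pp["value"].to_numpy())

    def test_zero_variance_degenerate(self):
        sc = pmgait.PMScoreSeries(subject_id="S", condition="100",
                                  fs_hz=150.0, pp=np.zeros((10, 3)))
        with pytest.raises(DegenerateInputError):
            pmgait.participant_rvar([sc])


class TestPrincipalAccelerations:
    fs = 150.0

    def _series(self, x):
        return pmgait.PMScoreSeries(subject_id="S", condition="100",
                                    fs_hz=self.fs, pp=np.column_stack([x]))

    def test_quadratic_gives_constant_second_derivative(self):
        t = np.arange(0, 2, 1 / self.fs)
        pa = pmgait.second_derivative(t**2, self.fs)
        np.testing.assert_allclose(pa[1:-1], 2.0, atol=1e-6)
        assert np.isnan(pa[0]) and np.isnan(pa[-1])

    def test_sine_amplitude_closed_form(self):
        # d^2/dt^2 [A sin(2 pi 2 t)] has amplitude (4 pi)^2 A
        a = 1.7
        t = np.arange(0, 8, 1 / self.fs)
        s = self._series(a * np.sin(2 * np.pi * 2 * t))
        out = pmgait.principal_accelerations(s, filter_scores=False)
        amp = np.nanmax(np.abs(out.pa[200:-200, 0]))
        assert amp == pytest.approx((4 * np.pi) ** 2 * a, rel=0.01)

    def test_zero_phase_filter_no_lag_at_3hz(self):
        t = np.arange(0, 8, 1 / self.fs)
        x = np.sin(2 * np.pi * 3 * t)
        y = pmgait.lowpass_filter(x, self.fs)
        xc = np.correlate(y[200:-200], x[200:-200], mode="full")
        lag = np.argmax(xc) - (len(y[200:-200]) - 1)
        # < 0.5 degree at 3 Hz is < 1/2160 s, i.e. lag 0 at 150 Hz
        assert lag == 0

    def test_20hz_probe_attenuated(self):
        t = np.arange(0, 8, 1 / self.fs)
        x = np.sin(2 * np.pi * 20 * t)
        y = pmgait.lowpass_filter(x, self.fs)
        assert y[200:-200].std() / x[200:-200].std() < 0.03

    def test_short_series_rejected(self):
        s = self._series(np.arange(10, dtype=float))
        with pytest.raises(ValidationError):
            pmgait.principal_accelerations(s)


class TestSpectralProfile:
    def test_pure_tone_peak_and_parseval(self):
        fs = 150.0
        t = np.arange(0, 16, 1 / fs)
        x = np.sin(2 * np.pi * 3 * t)
        sc = pmgait.PMScoreSeries(subject_id="S", condition="100", fs_hz=fs,
                                  pp=np.column_stack([x]))
        prof = pmgait.spectral_profile(sc)
        peak = prof["peak_hz"].iloc[0]
        assert peak == pytest.approx(3.0, abs=fs / len(t) + 1e-9)
        total = prof["total_power"].iloc[0]
        assert total == pytest.approx(x.var(), rel=1e-6)

    def test_stride_power_in_low_band(self, scores):
        prof = pmgait.spectral_profile(scores[0])
        pm1 = prof[prof["pm"] == 1].set_index("band_lo_hz")
        assert pm1.loc[0, "power"] > pm1.loc[5, "power"]
        assert pm1.loc[0, "power"] / pm1.loc[0, "total_power"] > 0.5


class TestLooRobustness:
    def test_identical_subjects_fully_robust(self, rng):
        base = rng.normal(size=(60, 6))
        trials = [_posture(base.copy(), subject=f"S{i}") for i in range(4)]
        report = pmgait.loo_robustness(pool(trials), k_check=3)
        assert (report.similarity["similarity"] > 1 - 1e-9).all()

    def test_similarity_bounded(self, pooled):
        report = pmgait.loo_robustness(pooled, k_check=5)
        sim = report.similarity["similarity"]
        assert ((sim >= 0) & (sim <= 1)).all()

    def test_planted_modes_robust_noise_mode_not(self, rng):
        # strong modes shared by all subjects on axes 0 and 3 (9:1); each
        # subject additionally carries a weak idiosyncratic direction, so
        # leading eigenvectors survive any leave-one-out while trailing
        # eigenvectors depend on who is in the sample
        trials = []
        for i in range(6):
            t = rng.normal(size=(400, 2)) * np.array([3.0, 1.0])
            x = rng.normal(scale=0.02, size=(400, 6))
            x[:, 0] += t[:, 0]
            x[:, 3] += t[:, 1]
            own = np.zeros(6)
            own[[1, 2, 4, 5]] = rng.normal(size=4)
            own /= np.linalg.norm(own)
            x += np.outer(rng.normal(scale=0.3, size=400), own)
            trials.append(_posture(x, subject=f"S{i}"))
        report = pmgait.loo_robustness(pool(trials), k_check=6)
        mins = report.min_similarity()
        assert mins[1] > 0.95 and mins[2] > 0.95
        assert mins[3:].min() < 0.8

    def test_too_few_subjects(self, rng):
        trials = [_posture(rng.normal(size=(20, 6)), subject=f"S{i}")
                  for i in range(2)]
        with pytest.raises(ValidationError):
            pmgait.loo_robustness(pool(trials))
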