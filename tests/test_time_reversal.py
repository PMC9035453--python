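"""Time-reversal decomposition, Tikhonov inversion, photon classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rmoct.time_reversal import (
    classify_photons,
    decompose,
    default_lambda_grid,
    marchenko_pastur_cdf,
    marchenko_pastur_threshold,
    open_channel_gain,
    photon_taxonomy,
    regularized_invert,
    select_lambda,
    tikhonov_filter,
)


def random_complex(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


class TestDecompose:
    def test_diagonal_matrix(self):
        trd = decompose(np.diag([3.0, 1.0]).astype(complex))
        np.testing.assert_allclose(trd.s, [3.0, 1.0])
        np.testing.assert_allclose(np.abs(trd.U), np.eye(2), atol=1e-12)
        np.testing.assert_allclose(trd.V, np.eye(2), atol=1e-12)

    def test_gram_eigenvalue_oracle(self, rng):
        """Singular values = sqrt of eigenvalues of R^dagger R."""
        R = random_complex(rng, (12, 9))
        trd = decompose(R)
        gram_eigs = np.sort(np.linalg.eigvalsh(R.conj().T @ R))[::-1]
        np.testing.assert_allclose(trd.s, np.sqrt(np.maximum(gram_eigs, 0)), atol=1e-10)

    def test_reconstruction(self, rng):
        R = random_complex(rng, (20, 15))
        trd = decompose(R)
        resid = np.linalg.norm(trd.reconstruct() - R) / np.linalg.norm(R)
        assert resid <= 1e-8

    def test_orthonormal_factors(self, rng):
        R = random_complex(rng, (14, 10))
        trd = decompose(R)
        np.testing.assert_allclose(trd.U.conj().T @ trd.U, np.eye(10), atol=1e-10)
        np.testing.assert_allclose(trd.V.conj().T @ trd.V, np.eye(10), atol=1e-10)

    def test_symmetric_matrix_takagi_gauge(self, rng):
        """For symmetric R the gauge aligns conj(U) with V (Takagi form),
        making V S V^T reproduce conj(R)."""
        A = random_complex(rng, (12, 12))
        R = A + A.T
        trd = decompose(R)
        em = (trd.V * trd.s) @ trd.V.T
        np.testing.assert_allclose(em, R.conj(), atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            decompose(np.array([[np.nan, 0], [0, 1]], dtype=complex))


class TestTikhonovFilter:
    def test_unregularized_limit(self):
        np.testing.assert_allclose(tikhonov_filter(np.array([2.0, 1.0]), 0.0), [1, 1])

    def test_zero_singular_value_at_zero_lambda(self):
        np.testing.assert_allclose(tikhonov_filter(np.array([1.0, 0.0]), 0.0), [1, 0])

    def test_half_at_lambda_equals_s(self):
        assert tikhonov_filter(np.array([0.7]), 0.7)[0] == pytest.approx(0.5)

    def test_grid_endpoint_suppression(self):
        """At the top of the published lambda grid, f = 1e-16 within one ulp."""
        f = tikhonov_filter(np.array([1.0]), 1e8)[0]
        assert f == pytest.approx(1e-16, rel=1e-12)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            tikhonov_filter(np.array([1.0]), -0.1)

    @given(lam=st.floats(1e-8, 1e8), s=st.floats(1e-12, 1e6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_filter_in_unit_interval(self, lam, s):
        f = tikhonov_filter(np.array([s]), lam)[0]
        assert 0.0 < f <= 1.0


class TestRegularizedInvert:
    def test_identity_matrix(self, rng):
        trd = decompose(np.eye(8, dtype=complex))
        e = random_complex(rng, 8)
        np.testing.assert_allclose(regularized_invert(trd, 0.0, e), e, atol=1e-12)

    @pytest.mark.parametrize("shape,lam", [((16, 16), 0.3), ((24, 12), 1.0),
                                           ((64, 64), 0.05), ((48, 64), 0.5)])
    def test_matches_ridge_closed_form(self, rng, shape, lam):
        """V F S^+ U^dagger equals (R^dagger R + lam^2 I)^-1 R^dagger."""
        R = random_complex(rng, shape)
        trd = decompose(R)
        e = random_complex(rng, shape[0])
        x = regularized_invert(trd, lam, e)
        direct = np.linalg.solve(
            R.conj().T @ R + lam ** 2 * np.eye(shape[1]), R.conj().T @ e
        )
        assert np.linalg.norm(x - direct) <= 1e-10 * np.linalg.norm(direct)

    def test_total_suppression_limit(self, rng):
        R = random_complex(rng, (10, 10))
        R /= np.linalg.norm(R, 2)
        trd = decompose(R)
        e = random_complex(rng, 10)
        x = regularized_invert(trd, 1e8, e)
        assert np.linalg.norm(x) <= 1e-14 * np.linalg.norm(e)

    def test_dimension_mismatch(self, rng):
        trd = decompose(random_complex(rng, (8, 6)))
        with pytest.raises(ValueError):
            regularized_invert(trd, 0.1, np.ones(7))


class TestSelectLambda:
    def test_default_grid_spans_published_range(self):
        grid = default_lambda_grid()
        assert grid[0] == pytest.approx(1e-8)
        assert grid[-1] == pytest.approx(1e8)
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, ratios[0])  # logarithmic spacing

    def test_noiseless_selects_smallest_lambda(self, rng):
        """Well-conditioned noiseless system: smallest grid value, eta ~ 0."""
        R = random_complex(rng, (8, 8)) + 4 * np.eye(8)
        trd = decompose(R)
        c = random_complex(rng, (8, 5))
        reg = select_lambda(trd, c, R @ c)
        assert reg.lam == pytest.approx(1e-8)
        assert reg.eta <= 1e-8

    def test_lambda_grows_with_noise(self, rng):
        """Selected lambda is non-decreasing in the noise level (median)."""
        lams = {sig: [] for sig in (1e-4, 1e-2, 1e-1)}
        for seed in range(20):
            r = np.random.default_rng(seed)
            R = random_complex(r, (24, 24))
            trd = decompose(R)
            c = random_complex(r, (24, 6))
            clean = R @ c
            for sig in lams:
                noisy = clean + sig * random_complex(r, clean.shape)
                lams[sig].append(select_lambda(trd, c, noisy).lam)
        med = [np.median(lams[s]) for s in (1e-4, 1e-2, 1e-1)]
        assert med[0] <= med[1] <= med[2]
        assert med[2] > med[0]

    def test_eta_curve_monotone_above_minimum_noiseless(self, rng):
        R = random_complex(rng, (10, 10)) + 3 * np.eye(10)
        trd = decompose(R)
        c = random_complex(rng, (10, 4))
        reg = select_lambda(trd, c, R @ c)
        k = int(np.argmin(reg.eta_curve))
        assert np.all(np.diff(reg.eta_curve[k:]) >= -1e-12)

    def test_degenerate_reference_rejected(self, rng):
        trd = decompose(random_complex(rng, (6, 6)))
        with pytest.raises(ValueError):
            select_lambda(trd, np.zeros((6, 2)), random_complex(rng, (6, 2)))

    def test_empty_probes_rejected(self, rng):
        trd = decompose(random_complex(rng, (6, 6)))
        with pytest.raises(ValueError):
            select_lambda(trd, np.empty((6, 0)), np.empty((6, 0)))


class TestClassification:
    def test_all_below_threshold(self):
        trd = decompose(np.diag([1.0, 1.0, 1.0, 1.0]).astype(complex))
        cls = classify_photons(trd, threshold=2.0)
        assert cls.frac_above == 0.0
        assert cls.frac_below == 100.0

    def test_energy_share_arithmetic(self):
        trd = decompose(np.diag([3.0, 1.0]).astype(complex))
        cls = classify_photons(trd, threshold=2.0)
        assert cls.frac_above == pytest.approx(90.0)

    def test_count_mode(self):
        trd = decompose(np.diag([3.0, 1.0]).astype(complex))
        cls = classify_photons(trd, threshold=2.0, mode="count")
        assert cls.frac_above == pytest.approx(50.0)

    def test_fractions_sum_to_100(self, rng):
        for _ in range(5):
            trd = decompose(random_complex(rng, (20, 15)))
            thr = float(np.median(trd.s))
            cls = classify_photons(trd, thr)
            assert cls.frac_above + cls.frac_below == pytest.approx(100.0, abs=1e-9)

    def test_planted_spike_recovery(self):
        """A planted strong channel's energy share is recovered within 1%."""
        rng = np.random.default_rng(0)
        m = 400
        noise = (rng.standard_normal((m, m)) + 1j * rng.standard_normal((m, m)))
        noise /= np.sqrt(2 * m)  # bulk edge ~ 2
        u = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        v = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        u /= np.linalg.norm(u); v /= np.linalg.norm(v)
        spike = 8.0
        R = noise + spike * np.outer(u, v.conj())
        trd = decompose(R)
        cls = classify_photons(trd, threshold=3.0)
        planted = 100 * spike ** 2 / (spike ** 2 + np.sum(np.abs(noise) ** 2))
        assert cls.frac_above == pytest.approx(planted, abs=1.0)

    def test_marchenko_pastur_bulk_spectrum(self):
        """Squared singular values of an iid matrix follow the MP law
        (Kolmogorov-Smirnov test over seeds)."""
        from scipy import stats

        pvals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m, n = 300, 150
            X = (rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))) / np.sqrt(2 * m)
            s = np.linalg.svd(X, compute_uv=False)
            beta = n / m
            ks = stats.kstest(s ** 2, lambda x: marchenko_pastur_cdf(x, beta))
            pvals.append(ks.pvalue)
        assert np.median(pvals) > 0.01

    def test_mp_threshold_sits_at_bulk_edge(self):
        rng = np.random.default_rng(3)
        m, n = 400, 200
        X = (rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))) / np.sqrt(2)
        s = np.linalg.svd(X, compute_uv=False)
        thr = marchenko_pastur_threshold(s, (m, n))
        assert thr == pytest.approx(s[0], rel=0.1)  # pure noise: edge ~ s_max

    def test_empty_spectrum_rejected(self):
        from rmoct.time_reversal import TimeReversalDecomposition

        trd = TimeReversalDecomposition(
            U=np.empty((4, 0)), s=np.empty(0), V=np.empty((4, 0))
        )
        with pytest.raises(ValueError):
            classify_photons(trd, 1.0)


class TestOpenChannelGain:
    def _cls(self, spectrum, thr, mode="energy"):
        return classify_photons(decompose(np.diag(spectrum).astype(complex)), thr, mode=mode)

    def test_identical_spectra_zero_gain(self):
        a = self._cls([3.0, 1.0], 2.0)
        b = self._cls([3.0, 1.0], 2.0)
        assert open_channel_gain(a, b) == 0.0

    def test_percentage_point_bookkeeping(self):
        """Before 1.14%, after 8.84% -> 7.70 percentage points gained."""
        from rmoct.time_reversal import PhotonClassification

        before = PhotonClassification(1.0, 1.14, 98.86, 1)
        after = PhotonClassification(1.0, 8.84, 91.16, 5)
        assert open_channel_gain(before, after) == pytest.approx(7.70)
        taxo = photon_taxonomy(before, after)
        assert taxo["frac_ss"] == pytest.approx(1.14)
        assert taxo["frac_ms1"] == pytest.approx(7.70)
        assert taxo["frac_ms2"] == pytest.approx(91.16)
        assert sum(taxo.values()) == pytest.approx(100.0, abs=0.01)

    def test_negative_gain_reported_not_clamped(self):
        a = self._cls([3.0, 1.0], 2.0)
        b = self._cls([1.0, 1.0], 2.0)
        assert open_channel_gain(a, b) == pytest.approx(-90.0)

    def test_threshold_mismatch_rejected(self):
        a = self._cls([3.0, 1.0], 2.0)
        b = self._cls([3.0, 1.0], 1.5)
        with pytest.raises(ValueError):
            open_channel_gain(a, b)
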