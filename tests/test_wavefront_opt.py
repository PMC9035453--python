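"""Matched wavefronts, reshaping, phase-only projection, re-acquisition."""

import numpy as np
import pytest

from rmoct.medium_sim import GridSpec, make_phantom
from rmoct.rm_acquisition import ScanGrid, acquire_rm, project_to_scan_basis
from rmoct.time_reversal import decompose
from rmoct.wavefront_opt import (
    StalenessError,
    WavefrontSet,
    fill_column,
    matched_wavefront,
    matched_wavefront_set,
    phase_only_project,
    reshape_to_2d,
    shaped_input_fields,
    shaped_reacquire,
)


class TestMatchedWavefront:
    def test_identity_rm_gives_delta(self, small_grid, small_scan):
        trd = decompose(np.eye(49, dtype=complex))
        k = matched_wavefront(trd, 0.0, (2, 3), small_grid, small_scan)
        i = small_scan.linear_index((2, 3))
        expect = np.zeros(49)
        expect[i] = 1.0
        np.testing.assert_allclose(np.abs(k), expect, atol=1e-10)

    def test_unitary_rm_is_phase_conjugation(self, rng, small_grid, small_scan):
        """For unitary R the regularized inverse at lambda=0 equals the
        conjugate of the target row (digital phase conjugation)."""
        A = rng.standard_normal((49, 49)) + 1j * rng.standard_normal((49, 49))
        Q, _ = np.linalg.qr(A)
        trd = decompose(Q)
        pt = (4, 4)
        i = small_scan.linear_index(pt)
        k = matched_wavefront(trd, 0.0, pt, small_grid, small_scan)
        expect = Q[i, :].conj()  # i-th column of Q^dagger
        expect = expect / np.linalg.norm(expect)
        # match up to a global phase
        phase = np.vdot(expect, k) / abs(np.vdot(expect, k))
        np.testing.assert_allclose(k, expect * phase, atol=1e-10)

    def test_output_concentration_well_conditioned(self, rng, small_grid, small_scan):
        """R k concentrates >= 99% of output energy on the target index."""
        R = (rng.standard_normal((49, 49)) + 1j * rng.standard_normal((49, 49))) / 7
        R += 4 * np.eye(49)
        trd = decompose(R)
        pt = (3, 5)
        i = small_scan.linear_index(pt)
        k = matched_wavefront(trd, 0.0, pt, small_grid, small_scan)
        out = R @ k
        assert np.abs(out[i]) ** 2 / np.sum(np.abs(out) ** 2) >= 0.99

    def test_invalid_target_rejected(self, small_grid, small_scan):
        trd = decompose(np.eye(49, dtype=complex))
        with pytest.raises(ValueError):
            matched_wavefront(trd, 0.0, (0, 4), small_grid, small_scan)


class TestReshaping:
    def test_round_trip_identity(self, rng, small_scan):
        k = rng.standard_normal(49) + 1j * rng.standard_normal(49)
        np.testing.assert_array_equal(fill_column(reshape_to_2d(k, small_scan)), k)

    def test_961_vector_maps_to_31x31(self):
        k = np.arange(961, dtype=complex)
        assert reshape_to_2d(k, ScanGrid(31, 2)).shape == (31, 31)

    def test_row_major_convention_anchor(self, small_scan):
        k = np.zeros(49)
        k[0] = 1.0
        m = reshape_to_2d(k, small_scan)
        assert m[0, 0] == 1.0

    def test_length_mismatch(self, small_scan):
        with pytest.raises(ValueError):
            reshape_to_2d(np.zeros(48), small_scan)


class TestPhaseOnly:
    def test_uniform_field_uniform_phase(self):
        w = np.full((4, 4), 2.0 * np.exp(1j * np.pi / 4))
        np.testing.assert_allclose(phase_only_project(w), np.pi / 4)

    def test_idempotent(self, rng):
        w = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        p1 = phase_only_project(w)
        p2 = phase_only_project(np.exp(1j * p1))
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_zero_pixels_get_zero_phase(self):
        w = np.array([0.0, 1j])
        np.testing.assert_allclose(phase_only_project(w), [0.0, np.pi / 2])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            phase_only_project(np.zeros((3, 3)))

    def test_pi_over_four_focusing_penalty(self):
        """Phase-only modulation through a random unitary keeps ~pi/4 of the
        full-conjugation focal intensity (N = 256 modes, within 10%)."""
        n = 256
        ratios = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            A = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
            Q, _ = np.linalg.qr(A)
            row = Q[0, :].conj()
            full = row / np.linalg.norm(row)
            phase_only = np.exp(1j * np.angle(row)) / np.sqrt(n)
            ratios.append(
                np.abs(Q[0] @ phase_only) ** 2 / np.abs(Q[0] @ full) ** 2
            )
        assert np.mean(ratios) == pytest.approx(np.pi / 4, rel=0.10)


class TestShapedReacquire:
    def test_phase_only_maps_unit_modulus(self, rng, small_scan, small_grid):
        k = rng.standard_normal((49, 3)) + 1j * rng.standard_normal((49, 3))
        wfs = WavefrontSet(
            k_columns=k, targets=((1, 1), (2, 2), (3, 3)), scan_grid=small_scan,
            grid=small_grid, depth_smfp=0.0, phantom_seed=None, lambda_used=0.0,
        )
        maps = wfs.phase_maps
        assert maps.shape == (3, 7, 7)
        assert np.all(np.abs(np.exp(1j * maps)) == pytest.approx(1.0))

    def test_coefficient_synthesis_reproduces_basis(self, small_scan, small_grid, small_fields):
        """A one-hot coefficient vector synthesizes the matching basis spot."""
        i = small_scan.linear_index((2, 5))
        k = np.zeros((49, 1), dtype=complex)
        k[i, 0] = 1.0
        wfs = WavefrontSet(
            k_columns=k, targets=((2, 5),), scan_grid=small_scan, grid=small_grid,
            depth_smfp=0.0, phantom_seed=None, lambda_used=0.0, modulation="complex",
        )
        sf = shaped_input_fields(wfs)
        overlap = abs(np.vdot(small_fields[i], sf[0]))
        assert overlap == pytest.approx(1.0, abs=1e-9)

    def test_staleness_guard(self, small_grid, small_scan, small_fields):
        ph_a = make_phantom(small_grid, depth_smfp=1.0, seed=1)
        ph_b = make_phantom(small_grid, depth_smfp=1.0, seed=2)
        rm = acquire_rm(ph_a, small_fields, small_scan)
        trd = decompose(project_to_scan_basis(rm, small_fields))
        wfs = matched_wavefront_set(
            trd, 0.1, [(4, 4)], small_grid, small_scan,
            depth_smfp=1.0, phantom_seed=ph_a.seed,
        )
        with pytest.raises(StalenessError):
            shaped_reacquire(ph_b, wfs)

    def test_free_space_shaping_is_noop(self, mirror_phantom, small_scan, small_fields):
        """Against a surface mirror there is nothing to correct: the shaped
        input for each target reproduces a focus at that target."""
        rm = acquire_rm(mirror_phantom, small_fields, small_scan)
        rs = project_to_scan_basis(rm, small_fields)
        trd = decompose(rs)
        wfs = matched_wavefront_set(
            trd, 0.1, list(small_scan.points()), mirror_phantom.grid, small_scan,
            depth_smfp=0.0, phantom_seed=mirror_phantom.seed, desired="patch",
        )
        rm_shaped = shaped_reacquire(mirror_phantom, wfs)
        rs_shaped = project_to_scan_basis(rm_shaped, small_fields)
        for pt in [(2, 2), (4, 4), (6, 3)]:
            i = small_scan.linear_index(pt)
            col = np.abs(rs_shaped.matrix[:, i]) ** 2
            assert col[i] / col.sum() >= 0.5  # dominant self-return

    def test_phase_only_bounded_by_complex_modulation(self, small_grid, small_scan, small_fields):
        """Delivered target energy under phase-only modulation never exceeds
        the full complex modulation, per target."""
        ph = make_phantom(small_grid, depth_smfp=2.0, seed=21)
        rm = acquire_rm(ph, small_fields, small_scan)
        trd = decompose(project_to_scan_basis(rm, small_fields))
        targets = [(2, 2), (4, 4), (6, 6)]
        delivered = {}
        for modu in ("complex", "phase_only"):
            wfs = matched_wavefront_set(
                trd, 0.3, targets, small_grid, small_scan,
                depth_smfp=2.0, phantom_seed=ph.seed, modulation=modu,
            )
            sf = shaped_input_fields(wfs)
            outs = acquire_rm(ph, sf, small_scan)
            rs = small_fields.reshape(49, -1) @ outs.matrix
            delivered[modu] = [
                np.abs(rs[small_scan.linear_index(t), j]) ** 2
                for j, t in enumerate(targets)
            ]
        for po, cm in zip(delivered["phase_only"], delivered["complex"]):
            assert po <= cm * 1.05  # small tolerance for noise-free numerics
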