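"""Matched incident wavefronts by regularized RM inversion.

For a desired focus at scan point i the matched input coefficient vector is
``k(i) = V F S^+ U^dagger e_des`` with ``e_des`` a delta (or Airy-weighted
patch) at the target's camera pixel — the Tikhonov-filtered inverse of the
reflection matrix.  Coefficients are reshaped to 2D phase maps following the
exact inverse of the RM column fill, optionally projected onto phase-only
modulation (the spatial-light-modulator constraint, which retains ~pi/4 of
the full-conjugation enhancement), pitch-matched, and re-acquired against the
same frozen phantom realization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .medium_sim import GridSpec, ScatteringPhantom
from .rm_acquisition import (
    ReflectionMatrix,
    ScanGrid,
    acquire_rm,
    aperture_mask,
    lens_focus,
)
from .time_reversal import TimeReversalDecomposition, regularized_invert
from .energy_map import airy_pattern

__all__ = [
    "WavefrontSet",
    "StalenessError",
    "matched_wavefront",
    "matched_wavefront_set",
    "reshape_to_2d",
    "fill_column",
    "phase_only_project",
    "shaped_input_fields",
    "shaped_reacquire",
]


class StalenessError(RuntimeError):
    """Wavefronts were optimized against a different phantom realization."""


def _desired_output(
    grid: GridSpec,
    scan_grid: ScanGrid,
    target_point: Tuple[int, int],
    n_out: int,
    mode: str = "delta",
    patch_radius_px: float = 3.0,
) -> np.ndarray:
    """Desired reflected field: a focus at the target point.

    Built in whichever output basis the decomposition uses: a delta at the
    target's scan index for a scan-projected (monostatic) RM, or at the
    target's camera pixel for a full pixel-basis RM; ``patch`` mode spreads
    the delta over an Airy-weighted spot.
    """
    if n_out == scan_grid.n_points:
        shape = (scan_grid.n_side, scan_grid.n_side)
        r, c = target_point[0] - 1, target_point[1] - 1
        scan_grid.pixel_offset(target_point)  # validates range
        radius = patch_radius_px / scan_grid.spacing_px
    else:
        shape = (grid.n, grid.n)
        r, c = scan_grid.pixel_index(target_point, grid)
        radius = patch_radius_px
    if mode == "delta":
        e = np.zeros(shape, dtype=complex)
        e[r, c] = 1.0
    elif mode == "patch":
        e = np.sqrt(airy_pattern(shape, (r, c), radius)).astype(complex)
        e /= np.linalg.norm(e)
    else:
        raise ValueError("mode must be 'delta' or 'patch'")
    return e.reshape(-1)


def matched_wavefront(
    trd: TimeReversalDecomposition,
    lam: float,
    target_point: Tuple[int, int],
    grid: GridSpec,
    scan_grid: ScanGrid,
    desired: str = "delta",
) -> np.ndarray:
    """Matched input coefficient vector for one target scan point.

    The regularized inverse is applied to the desired output (a delta at the
    target's camera pixel by default) and the result is normalized to unit
    power, so enhancement comparisons measure redistribution of energy rather
    than injected power.
    """
    e_des = _desired_output(grid, scan_grid, target_point, trd.U.shape[0], mode=desired)
    k = regularized_invert(trd, lam, e_des)
    norm = np.linalg.norm(k)
    if norm == 0:
        raise ValueError("degenerate matched wavefront (zero norm)")
    return k / norm


def reshape_to_2d(k: np.ndarray, scan_grid: ScanGrid) -> np.ndarray:
    """Reshape an input coefficient vector to its 2D scan-grid map.

    Exact inverse of the row-major RM column fill; round-trips with
    :func:`fill_column`.
    """
    k = np.asarray(k)
    if k.size != scan_grid.n_points:
        raise ValueError("vector length does not match the scan grid")
    return k.reshape(scan_grid.n_side, scan_grid.n_side)


def fill_column(map2d: np.ndarray) -> np.ndarray:
    """Row-major flattening of a 2D map into an RM-style column vector."""
    return np.asarray(map2d).reshape(-1)


def phase_only_project(wavefront: np.ndarray) -> np.ndarray:
    """Phase-only modulation constraint: keep the argument, drop amplitude.

    Zero-amplitude pixels get phase 0.  Idempotent by construction.
    """
    w = np.asarray(wavefront)
    if not np.any(w != 0):
        raise ValueError("degenerate all-zero wavefront")
    return np.where(w == 0, 0.0, np.angle(w))


@dataclass
class WavefrontSet:
    """Matched wavefronts for a set of target points at one depth.

    ``k_columns[:, j]`` is the unit-power input coefficient vector for target
    ``targets[j]``; ``phase_maps[j]`` its 2D scan-grid phase map.
    """

    k_columns: np.ndarray
    targets: tuple
    scan_grid: ScanGrid
    grid: GridSpec
    depth_smfp: float
    phantom_seed: int | None
    lambda_used: float
    modulation: str = "phase_only"

    @property
    def phase_maps(self) -> np.ndarray:
        maps = np.empty((len(self.targets), self.scan_grid.n_side, self.scan_grid.n_side))
        for j in range(len(self.targets)):
            maps[j] = phase_only_project(
                reshape_to_2d(self.k_columns[:, j], self.scan_grid)
            )
        return maps


def matched_wavefront_set(
    trd: TimeReversalDecomposition,
    lam: float,
    targets: Sequence[Tuple[int, int]],
    grid: GridSpec,
    scan_grid: ScanGrid,
    depth_smfp: float = 0.0,
    phantom_seed: int | None = None,
    modulation: str = "phase_only",
    desired: str = "delta",
) -> WavefrontSet:
    """Matched wavefronts for many targets (vectorized over targets)."""
    cols = np.stack(
        [
            matched_wavefront(trd, lam, t, grid, scan_grid, desired=desired)
            for t in targets
        ],
        axis=1,
    )
    return WavefrontSet(
        k_columns=cols,
        targets=tuple(targets),
        scan_grid=scan_grid,
        grid=grid,
        depth_smfp=depth_smfp,
        phantom_seed=phantom_seed,
        lambda_used=lam,
        modulation=modulation,
    )


def _coefficient_lattice(k_cols: np.ndarray, scan_grid: ScanGrid, grid: GridSpec) -> np.ndarray:
    """Embed scan-basis coefficient vectors on the field grid's focal lattice."""
    m = k_cols.shape[1]
    lattice = np.zeros((m, grid.n, grid.n), dtype=complex)
    for i, pt in enumerate(scan_grid.points()):
        r, c = scan_grid.pixel_index(pt, grid)
        lattice[:, r, c] = k_cols[i, :]
    return lattice


def shaped_input_fields(
    wfs: WavefrontSet,
    aperture_radius_px: float | None = None,
) -> np.ndarray:
    """Physical incident fields realizing the matched wavefronts.

    The SLM-plane field is the pupil-masked superposition of the scan ramps
    weighted by the matched coefficients (computed as an inverse lens
    transform of the coefficient lattice).  Under ``phase_only`` modulation
    the SLM keeps only the argument of that superposition.  Every field is
    normalized to unit power.
    """
    grid, scan_grid = wfs.grid, wfs.scan_grid
    lattice = _coefficient_lattice(wfs.k_columns, scan_grid, grid)
    # pupil-plane superposition of the scan ramps weighted by the matched
    # coefficients: the inverse of the ideal-lens transform applied to the
    # coefficient lattice on the focal raster
    slm = np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(lattice, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    ) * grid.n
    pupil = aperture_mask(grid, aperture_radius_px)
    if wfs.modulation == "phase_only":
        slm = pupil[None] * np.exp(1j * np.angle(slm))
    elif wfs.modulation == "complex":
        slm = pupil[None] * slm
    else:
        raise ValueError("modulation must be 'phase_only' or 'complex'")
    fields = lens_focus(slm)
    power = np.sum(np.abs(fields) ** 2, axis=(-2, -1), keepdims=True)
    if np.any(power == 0):
        raise ValueError("degenerate shaped field")
    return fields / np.sqrt(power)


def shaped_reacquire(
    phantom: ScatteringPhantom,
    wfs: WavefrontSet,
    aperture_radius_px: float | None = None,
    snr_db: float | None = None,
    noise_floor: float | None = None,
    noise_seed: int = 1,
) -> ReflectionMatrix:
    """Re-acquire the reflection matrix with matched-wavefront inputs.

    Guards against comparing across scattering realizations: the phantom seed
    must match the one the wavefronts were optimized for.
    """
    if wfs.phantom_seed is not None and wfs.phantom_seed != phantom.seed:
        raise StalenessError(
            f"wavefronts were optimized for phantom seed {wfs.phantom_seed}, "
            f"got {phantom.seed}"
        )
    fields = shaped_input_fields(wfs, aperture_radius_px=aperture_radius_px)
    return acquire_rm(
        phantom,
        fields,
        wfs.scan_grid,
        snr_db=snr_db,
        noise_floor=noise_floor,
        noise_seed=noise_seed,
    )
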