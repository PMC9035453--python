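"""Scanning input basis, lock-in demodulation model and RM assembly.

The incident basis is a raster of focused spots: each of the ``n_side**2``
SLM phase ramps steers an ideal lens focus to one scan position inside the
field of view (Fourier-shift relation).  For every input the camera-conjugate
double-pass output field is reshaped row-major and filled into one column of
the reflection matrix R, so column order equals scan order.

The heterodyne detection chain of the physical instrument is represented by
an idealized quadrature lock-in model: the beat-note intensity frames are
demodulated at the beat frequency to recover the complex sample field exactly
on noiseless synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage

from .medium_sim import ComplexField, GridSpec, ScatteringPhantom, reflect_stack

__all__ = [
    "ScanGrid",
    "ReflectionMatrix",
    "make_phase_ramps",
    "aperture_mask",
    "lens_focus",
    "ramp_input_fields",
    "acquire_rm",
    "project_to_scan_basis",
    "lockin_demodulate",
    "synthetic_beat_frames",
    "beat_frequency",
    "resample_camera_to_slm",
]


@dataclass(frozen=True)
class ScanGrid:
    """Raster of focal-spot scan positions on the field grid.

    Scan indices are 1-based, ``(1, 1)`` to ``(n_side, n_side)``; position
    ``(row, col)`` maps to a field-grid pixel offset of ``spacing_px`` pixels
    per scan step from the grid centre.  The default 31 x 31 raster with
    2-pixel spacing covers the 70 x 70 um field of view with 961 points.
    """

    n_side: int = 31
    spacing_px: int = 2

    def __post_init__(self) -> None:
        if self.n_side < 3 or self.n_side % 2 == 0:
            raise ValueError("n_side must be odd and >= 3")
        if self.spacing_px < 1:
            raise ValueError("spacing_px must be >= 1")

    @property
    def n_points(self) -> int:
        return self.n_side ** 2

    def pixel_offset(self, point: Tuple[int, int]) -> Tuple[int, int]:
        """Field-pixel offset from grid centre of a 1-based scan point."""
        r, c = point
        if not (1 <= r <= self.n_side and 1 <= c <= self.n_side):
            raise ValueError(f"scan point {point} outside {self.n_side}x{self.n_side} grid")
        half = (self.n_side - 1) // 2
        return ((r - 1 - half) * self.spacing_px, (c - 1 - half) * self.spacing_px)

    def pixel_index(self, point: Tuple[int, int], grid: GridSpec) -> Tuple[int, int]:
        """Absolute field-grid pixel (row, col) of a 1-based scan point."""
        dr, dc = self.pixel_offset(point)
        r, c = grid.n // 2 + dr, grid.n // 2 + dc
        if not (0 <= r < grid.n and 0 <= c < grid.n):
            raise ValueError(f"scan point {point} maps outside the field grid")
        return r, c

    def points(self):
        """All scan points in row-major order (1-based)."""
        for r in range(1, self.n_side + 1):
            for c in range(1, self.n_side + 1):
                yield (r, c)

    def linear_index(self, point: Tuple[int, int]) -> int:
        r, c = point
        self.pixel_offset(point)  # validates range
        return (r - 1) * self.n_side + (c - 1)


def aperture_mask(grid: GridSpec, radius_px: float | None = None) -> np.ndarray:
    """Circular pupil mask on the SLM/pupil plane (centred, top-hat).

    The default radius of ``n/4`` frequency pixels keeps the numerical
    aperture (hence the focal-spot size in physical units) independent of the
    simulation window: the first Airy null falls 4.88 field pixels from the
    focus, about 1.2 scan steps on the default raster.
    """
    if radius_px is None:
        radius_px = grid.n / 4.0
    idx = np.arange(grid.n) - grid.n // 2
    r2 = idx[:, None] ** 2 + idx[None, :] ** 2
    return (r2 <= radius_px ** 2).astype(float)


def lens_focus(slm_field: np.ndarray) -> np.ndarray:
    """Ideal-lens (centred unitary FFT) map from pupil plane to focal plane."""
    n = slm_field.shape[-1]
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(slm_field, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    ) / n


def make_phase_ramps(
    scan_grid: ScanGrid, grid: GridSpec
) -> np.ndarray:
    """Linear SLM phase ramps steering the focus to each scan position.

    Returns an array of shape (n_points, n, n) of phase maps in radians,
    row-major over the scan grid.  Ramp i, focused by :func:`lens_focus`
    through the pupil, places the focal-spot centroid at scan position i; the
    centre scan point gets the flat (zero-slope) map.  Positions beyond the
    grid Nyquist angle raise a range error.
    """
    n = grid.n
    idx = np.arange(n) - n // 2
    ramps = np.empty((scan_grid.n_points, n, n))
    for i, pt in enumerate(scan_grid.points()):
        dr, dc = scan_grid.pixel_offset(pt)
        if abs(dr) > n // 2 - 1 or abs(dc) > n // 2 - 1:
            raise ValueError(f"scan point {pt} beyond the steerable (Nyquist) range")
        phase = 2.0 * np.pi * (dr * idx[:, None] + dc * idx[None, :]) / n
        ramps[i] = np.angle(np.exp(1j * phase))  # wrap into (-pi, pi]
    return ramps


def ramp_input_fields(
    scan_grid: ScanGrid,
    grid: GridSpec,
    aperture_radius_px: float | None = None,
    dtype=np.complex128,
) -> np.ndarray:
    """Unit-power focal fields of all scan ramps (shape (n_points, n, n)).

    Each field is the ideal-lens focus of the pupil-masked ramp: a
    diffraction-limited Airy-like spot centred on its scan position.
    """
    ramps = make_phase_ramps(scan_grid, grid)
    pupil = aperture_mask(grid, aperture_radius_px)
    fields = lens_focus(pupil[None, :, :] * np.exp(1j * ramps)).astype(dtype)
    power = np.sum(np.abs(fields) ** 2, axis=(-2, -1), keepdims=True)
    return fields / np.sqrt(power)


@dataclass
class ReflectionMatrix:
    """Complex reflection matrix R: output pixels x scan inputs.

    ``matrix[p, i]`` is the camera-conjugate output field at pixel ``p``
    (row-major) for unit-power input ``i``; ``E_out = R @ E_in`` for input
    coefficient vectors in the scan basis.
    """

    matrix: np.ndarray
    grid: GridSpec
    scan_grid: ScanGrid
    depth_smfp: float = 0.0
    phantom_seed: int | None = None
    snr_db: float | None = None
    input_basis: str = "focused-spot"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("R must be 2D")
        if self.matrix.shape[1] > self.scan_grid.n_points:
            raise ValueError("more columns than scan points")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("R contains non-finite entries")

    @property
    def n_out(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_in(self) -> int:
        return self.matrix.shape[1]

    def column_field(self, i: int) -> ComplexField:
        """Column i reshaped back to the 2D camera-conjugate field."""
        data = self.matrix[:, i].reshape(self.grid.n, self.grid.n)
        return ComplexField(data, self.grid, "camera")


def acquire_rm(
    phantom: ScatteringPhantom,
    input_fields: np.ndarray | Sequence[ComplexField],
    scan_grid: ScanGrid,
    snr_db: float | None = None,
    noise_floor: float | None = None,
    noise_seed: int = 0,
    chunk: int = 256,
) -> ReflectionMatrix:
    """Acquire the reflection matrix for a set of incident fields.

    Each input is double-pass reflected from the phantom's target plane and
    the resulting 2D camera-conjugate field is reshaped row-major into one
    column of R (column order = input order).  Detection noise is additive
    complex Gaussian per camera pixel, specified either relative to the
    acquired signal (``snr_db``, acquisition-wide RMS signal over RMS noise)
    or as an absolute per-pixel standard deviation ``noise_floor`` in units
    of the unit-power inputs.  An absolute floor models a lock-in detector
    whose noise does not shrink with the depth-attenuated signal, so deep
    acquisitions become noise-dominated as in heterodyne practice.
    """
    if isinstance(input_fields, np.ndarray):
        stack = input_fields
    else:
        stack = np.stack([f.data for f in input_fields])
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("input_fields must be a non-empty stack of 2D fields")
    if stack.shape[-1] != phantom.grid.n:
        raise ValueError("input fields do not match the phantom grid")
    n = phantom.grid.n
    m = stack.shape[0]
    cols = np.empty((n * n, m), dtype=stack.dtype if np.iscomplexobj(stack) else complex)
    for start in range(0, m, chunk):
        out = reflect_stack(stack[start : start + chunk], phantom)
        cols[:, start : start + chunk] = out.reshape(out.shape[0], -1).T
    if snr_db is not None and noise_floor is not None:
        raise ValueError("specify either snr_db or noise_floor, not both")
    sigma = None
    if snr_db is not None:
        rms_signal = np.sqrt(np.mean(np.abs(cols) ** 2))
        sigma = rms_signal / 10.0 ** (snr_db / 20.0)
    elif noise_floor is not None:
        sigma = float(noise_floor)
    if sigma:
        rng = np.random.default_rng(noise_seed)
        noise = (
            rng.standard_normal(cols.shape) + 1j * rng.standard_normal(cols.shape)
        ) * (sigma / np.sqrt(2.0))
        cols = cols + noise.astype(cols.dtype)
    return ReflectionMatrix(
        matrix=cols,
        grid=phantom.grid,
        scan_grid=scan_grid,
        depth_smfp=phantom.depth_smfp,
        phantom_seed=phantom.seed,
        snr_db=snr_db,
    )


def project_to_scan_basis(
    R: ReflectionMatrix, input_fields: np.ndarray
) -> ReflectionMatrix:
    """Project the camera-pixel outputs onto the scan (focused-spot) basis.

    Returns the square monostatic reflection matrix ``R_s = B^T R`` where the
    columns of ``B`` are the flattened input basis fields.  With input and
    output expressed in the same basis, optical reciprocity makes ``R_s``
    symmetric; detection noise breaks the symmetry slightly, so the matrix is
    symmetrized explicitly (which also averages down the noise).  The
    symmetric monostatic RM is the natural container for the time-reversal
    decomposition and the model energy matrix.
    """
    b = np.asarray(input_fields).reshape(len(input_fields), -1)
    if b.shape[1] != R.n_out:
        raise ValueError("basis fields do not match the camera grid")
    rs = b @ R.matrix
    if rs.shape[0] == rs.shape[1]:
        rs = 0.5 * (rs + rs.T)
    return ReflectionMatrix(
        matrix=rs,
        grid=R.grid,
        scan_grid=R.scan_grid,
        depth_smfp=R.depth_smfp,
        phantom_seed=R.phantom_seed,
        snr_db=R.snr_db,
        input_basis=R.input_basis + "/scan-projected",
    )


# ---------------------------------------------------------------------------
# Idealized heterodyne lock-in detection
# ---------------------------------------------------------------------------


def beat_frequency(f_aom1_hz: float, f_aom2_hz: float) -> float:
    """Heterodyne beat frequency of the two acousto-optic modulators."""
    return abs(f_aom2_hz - f_aom1_hz)


def synthetic_beat_frames(
    field: np.ndarray,
    f_beat_hz: float,
    frame_rate_hz: float,
    n_periods: int = 1,
    reference_power: float = 1.0,
    noise_std: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate the intensity frames a lock-in camera would record.

    ``I_k = |E_r|^2 + |E_s|^2 + 2 sqrt(P_ref) |E_s| cos(2 pi f t_k + phase)``
    with optional additive Gaussian frame noise.
    """
    field = np.asarray(field)
    spp = frame_rate_hz / f_beat_hz
    n_frames = int(round(spp * n_periods))
    t = np.arange(n_frames) / frame_rate_hz
    amp = np.abs(field)
    ph = np.angle(field)
    frames = (
        reference_power
        + amp[None, ...] ** 2
        + 2.0
        * np.sqrt(reference_power)
        * amp[None, ...]
        * np.cos(2.0 * np.pi * f_beat_hz * t.reshape((-1,) + (1,) * field.ndim) + ph[None, ...])
    )
    if noise_std > 0:
        rng = rng or np.random.default_rng()
        frames = frames + noise_std * rng.standard_normal(frames.shape)
    return frames


def lockin_demodulate(
    intensity_frames: np.ndarray,
    f_beat_hz: float,
    frame_rate_hz: float,
    reference_power: float,
) -> np.ndarray:
    """Quadrature demodulation of beat-note intensity frames.

    Requires at least four equally spaced samples per beat period and an
    integer number of periods; returns the complex sample field per pixel,
    ``amplitude = sqrt(Ic^2 + Is^2) / (2 sqrt(P_ref))``,
    ``phase = atan2(Is, Ic)``.  Exact for noiseless synthetic beats.
    """
    if reference_power <= 0:
        raise ValueError("reference_power must be positive")
    frames = np.asarray(intensity_frames, dtype=float)
    n_frames = frames.shape[0]
    spp = frame_rate_hz / f_beat_hz
    if spp < 4 - 1e-9:
        raise ValueError("aliasing: need >= 4 samples per beat period")
    n_periods = n_frames / spp
    if abs(n_periods - round(n_periods)) > 1e-9 or round(n_periods) < 1:
        raise ValueError("frame count must cover an integer number of beat periods")
    t = np.arange(n_frames) / frame_rate_hz
    w = 2.0 * np.pi * f_beat_hz * t
    shape = (-1,) + (1,) * (frames.ndim - 1)
    ic = (2.0 / n_frames) * np.sum(frames * np.cos(w).reshape(shape), axis=0)
    is_ = (2.0 / n_frames) * np.sum(frames * np.sin(w).reshape(shape), axis=0)
    return (ic - 1j * is_) / (2.0 * np.sqrt(reference_power))


# ---------------------------------------------------------------------------
# Camera -> SLM pitch matching
# ---------------------------------------------------------------------------


def resample_camera_to_slm(phase_map: np.ndarray, factor: int = 5) -> np.ndarray:
    """Upsample a phase map from camera pitch to SLM pitch.

    The camera pixel pitch is ``factor`` times the SLM pitch, so an
    ``m x m`` map becomes ``factor*m x factor*m``.  Interpolation acts on the
    unit-modulus phasor (not the raw, wrapped phase) and the argument is taken
    afterwards, which is safe across the +-pi branch cut; constant maps are
    preserved exactly.
    """
    if not isinstance(factor, (int, np.integer)):
        raise ValueError("resampling factor must be an integer")
    if factor < 1:
        raise ValueError("resampling factor must be >= 1")
    z = np.exp(1j * np.asarray(phase_map, dtype=float))
    kwargs = dict(zoom=factor, order=1, mode="nearest", grid_mode=True)
    re = ndimage.zoom(z.real, **kwargs)
    im = ndimage.zoom(z.imag, **kwargs)
    return np.angle(re + 1j * im)
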