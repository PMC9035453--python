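"""Synthetic layered scattering phantoms and split-step beam propagation.

The scattering medium is modelled as a stack of thin Gaussian-correlated random
phase screens separated by free-space gaps, traversed twice (in and out) in a
reflection geometry.  Scattering strength is calibrated in units of the
scattering mean free path (SMFP): for a Gaussian random phase of variance
``sigma**2`` the ballistic (unscattered, DC) power transmitted through one
screen is ``exp(-sigma**2)``, so a stack of ``n`` screens with per-screen
standard deviation ``sqrt(d / n)`` attenuates the ballistic component by
``exp(-d)`` — the defining property of an optical depth of ``d`` SMFP.

Propagation uses the angular-spectrum (split-step Fourier) method.  On the
default grids every transverse spatial frequency is propagating (no evanescent
components), so each free-space step and each unit-modulus phase screen is
unitary and total power is conserved to machine precision; the only losses are
the cosine-taper absorbing frame at the grid boundary, which are tracked
separately.  Every elementary operator is a symmetric matrix in the pixel
basis, so the double-pass reflection operator is symmetric (reciprocal medium).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "GridSpec",
    "ComplexField",
    "ScatteringPhantom",
    "calibrate_screen_strength",
    "default_n_screens",
    "make_phantom",
    "propagate",
    "reflect_from_target",
    "reflect_stack",
    "ballistic_transmission_mc",
]

PLANES = ("slm", "surface", "target", "camera")


@dataclass(frozen=True)
class GridSpec:
    """Square pixel grid holding a sampled complex field.

    Parameters
    ----------
    n : int
        Pixels per side (even, >= 16).
    pitch_um : float
        Pixel pitch in micrometres.  The default covers the 70 x 70 um
        field of view with 64 pixels.
    wavelength_um : float
        Vacuum wavelength in micrometres.
    """

    n: int = 64
    pitch_um: float = 70.0 / 64.0
    wavelength_um: float = 0.8

    def __post_init__(self) -> None:
        if self.n < 16 or self.n % 2:
            raise ValueError("grid size must be even and >= 16")
        if self.pitch_um <= 0 or self.wavelength_um <= 0:
            raise ValueError("pitch and wavelength must be positive")

    @property
    def extent_um(self) -> float:
        return self.n * self.pitch_um

    @property
    def k0(self) -> float:
        """Vacuum wavenumber in rad/um."""
        return 2.0 * np.pi / self.wavelength_um

    def transverse_k(self) -> Tuple[np.ndarray, np.ndarray]:
        """FFT-ordered transverse wavenumbers (rad/um) along each axis."""
        k = 2.0 * np.pi * np.fft.fftfreq(self.n, d=self.pitch_um)
        return k[:, None], k[None, :]

    def free_space_transfer(self, dz_um: float) -> np.ndarray:
        """Angular-spectrum transfer function for a free-space step ``dz_um``.

        Propagating components acquire the exact phase ``exp(i kz dz)``;
        evanescent components (none on the default grid) always decay,
        regardless of the sign of ``dz``.
        """
        ky, kx = self.transverse_k()
        kz2 = self.k0 ** 2 - ky ** 2 - kx ** 2
        kz = np.sqrt(np.abs(kz2))
        h = np.where(
            kz2 >= 0,
            np.exp(1j * kz * dz_um),
            np.exp(-kz * abs(dz_um)),
        )
        return h


@dataclass
class ComplexField:
    """2D complex field sampled on a :class:`GridSpec`.

    ``absorbed_power`` accumulates energy removed by the boundary absorber
    during propagation that produced this field (zero for fields built
    directly).
    """

    data: np.ndarray
    grid: GridSpec
    plane: str = "camera"
    absorbed_power: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != (self.grid.n, self.grid.n):
            raise ValueError("field shape does not match grid")
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field contains non-finite entries")

    def power(self) -> float:
        """Total power sum(|E|^2)."""
        return float(np.sum(np.abs(self.data) ** 2))


def calibrate_screen_strength(depth_smfp: float, n_screens: int) -> float:
    """Per-screen phase standard deviation realizing an optical depth.

    For a zero-mean Gaussian phase of variance sigma^2 the ensemble-average
    ballistic amplitude transmission is ``exp(-sigma^2 / 2)`` and the ballistic
    power transmission ``exp(-sigma^2)``.  Per-screen attenuations multiply, so
    ``sigma = sqrt(depth_smfp / n_screens)`` makes the whole stack transmit
    ``exp(-depth_smfp)`` ballistically, independent of ``n_screens``.
    """
    if not np.isfinite(depth_smfp) or depth_smfp < 0:
        raise ValueError("depth_smfp must be finite and non-negative")
    if n_screens < 1:
        raise ValueError("n_screens must be >= 1")
    return float(np.sqrt(depth_smfp / n_screens))


def default_n_screens(depth_smfp: float) -> int:
    """Default screen count: two screens per SMFP of optical depth."""
    return max(1, int(round(2.0 * depth_smfp)))


def _gaussian_phase_screen(
    rng: np.random.Generator, n: int, corr_length_px: float, std: float
) -> np.ndarray:
    """Gaussian random phase screen with Gaussian autocorrelation.

    White Gaussian noise is filtered in Fourier space with the kernel
    ``exp(-k^2 l^2 / 4)`` (autocorrelation ``exp(-r^2 / l^2)``) and rescaled by
    the analytic filter power so the ensemble variance is exactly ``std**2``
    — a deterministic normalization that preserves Gaussianity, hence the
    exact ``exp(-std**2)`` ballistic attenuation.
    """
    white = rng.standard_normal((n, n))
    f = np.fft.fftfreq(n)
    k2 = (2.0 * np.pi) ** 2 * (f[:, None] ** 2 + f[None, :] ** 2)
    filt = np.exp(-k2 * corr_length_px ** 2 / 4.0)
    screen = np.fft.ifft2(np.fft.fft2(white) * filt).real
    var = float(np.sum(filt ** 2)) / n ** 2
    return std * screen / np.sqrt(var)


def _absorber_window(n: int, width_px: int) -> np.ndarray:
    """Cosine-taper absorbing frame (1 in the interior, -> 0 at the edge)."""
    w = np.ones(n)
    if width_px > 0:
        ramp = np.sin(0.5 * np.pi * (np.arange(width_px) + 0.5) / width_px) ** 2
        w[:width_px] = ramp
        w[-width_px:] = ramp[::-1]
    return w[:, None] * w[None, :]


@dataclass
class ScatteringPhantom:
    """Frozen realization of a layered scattering medium.

    ``screens`` holds the per-screen phase maps (radians); ``gap_um`` is the
    simulated free-space gap between consecutive screens.  The physical
    thickness implied by ``depth_smfp * smfp_um`` is recorded as metadata;
    the simulated optical path is compressed so the field of view can contain
    the beam (see package docs).
    """

    grid: GridSpec
    smfp_um: float
    depth_smfp: float
    n_screens: int
    screen_phase_std: float
    screens: np.ndarray
    target_reflectivity: np.ndarray
    seed: int
    gap_um: float = 4.0
    corr_length_px: float = 2.0
    absorber_px: int = 8
    absorber_on: bool = True

    @property
    def thickness_um(self) -> float:
        """Physical thickness implied by the optical depth (metadata)."""
        return self.depth_smfp * self.smfp_um

    @property
    def sim_path_um(self) -> float:
        """One-way simulated propagation distance through the stack."""
        if self.depth_smfp == 0:
            return 0.0
        return self.n_screens * self.gap_um

    def with_target(self, target_reflectivity: np.ndarray) -> "ScatteringPhantom":
        t = np.asarray(target_reflectivity, dtype=float)
        if t.shape != (self.grid.n, self.grid.n):
            raise ValueError("target map shape does not match grid")
        return replace(self, target_reflectivity=t)


def make_phantom(
    grid: GridSpec,
    smfp_um: float = 52.8,
    depth_smfp: float = 7.2,
    n_screens: int | None = None,
    target_reflectivity: np.ndarray | None = None,
    seed: int = 0,
    gap_um: float = 4.0,
    corr_length_px: float = 2.0,
    absorber_px: int = 8,
) -> ScatteringPhantom:
    """Build a scattering phantom with calibrated screen strength.

    The per-screen phase standard deviation is set by
    :func:`calibrate_screen_strength` so the stack's ballistic transmission is
    ``exp(-depth_smfp)``.  Identical parameters and seed give bit-identical
    screens.  ``target_reflectivity`` defaults to a uniform unit reflector at
    the imaging plane.
    """
    if not np.isfinite(smfp_um) or smfp_um <= 0:
        raise ValueError("smfp_um must be finite and positive")
    if not np.isfinite(depth_smfp) or depth_smfp < 0:
        raise ValueError("depth_smfp must be finite and non-negative")
    if n_screens is None:
        n_screens = default_n_screens(depth_smfp)
    if n_screens < 1:
        raise ValueError("n_screens must be >= 1")
    if target_reflectivity is None:
        target_reflectivity = np.ones((grid.n, grid.n))
    target_reflectivity = np.asarray(target_reflectivity, dtype=float)
    if target_reflectivity.shape != (grid.n, grid.n):
        raise ValueError("target map shape does not match grid")

    std = calibrate_screen_strength(depth_smfp, n_screens)
    rng = np.random.default_rng(seed)
    if std == 0.0:
        screens = np.zeros((n_screens, grid.n, grid.n))
    else:
        screens = np.stack(
            [
                _gaussian_phase_screen(rng, grid.n, corr_length_px, std)
                for _ in range(n_screens)
            ]
        )
    return ScatteringPhantom(
        grid=grid,
        smfp_um=smfp_um,
        depth_smfp=depth_smfp,
        n_screens=n_screens,
        screen_phase_std=std,
        screens=screens,
        target_reflectivity=target_reflectivity,
        seed=seed,
        gap_um=gap_um,
        corr_length_px=corr_length_px,
        absorber_px=absorber_px,
    )


# ---------------------------------------------------------------------------
# Split-step propagation
# ---------------------------------------------------------------------------


def _stack_ops(phantom: ScatteringPhantom):
    """Ordered elementary operators from camera-conjugate plane to target.

    Layout: an ideal relay back-propagates the target-conjugate field by the
    stack length L = n_screens * gap_um, then the field traverses
    half-gap, screen_1, gap, screen_2, ..., screen_n, half-gap.  Each operator
    is a symmetric matrix in the pixel basis, so applying them in reverse
    order realizes the transpose (reciprocal) return path.  A depth-0 phantom
    has zero extent: the operator list is empty (perfect surface mirror).
    """
    ops = []
    if phantom.depth_smfp == 0 or (
        phantom.screen_phase_std == 0.0 and phantom.sim_path_um == 0.0
    ):
        return ops
    g = phantom.gap_um
    L = phantom.sim_path_um
    ops.append(("fs", -L))
    ops.append(("fs", 0.5 * g))
    ops.append(("absorb", None))
    for i in range(phantom.n_screens):
        ops.append(("screen", i))
        if i < phantom.n_screens - 1:
            ops.append(("fs", g))
        else:
            ops.append(("fs", 0.5 * g))
        ops.append(("absorb", None))
    return ops


def _apply_ops(arr: np.ndarray, phantom: ScatteringPhantom, reverse: bool):
    """Apply the phantom's operator chain to a field or stack of fields.

    ``arr`` has shape (..., n, n).  Returns (out, absorbed_power) where
    ``absorbed_power`` has shape (...) and is zero when the absorber is off.
    """
    grid = phantom.grid
    ops = _stack_ops(phantom)
    if reverse:
        ops = ops[::-1]
    out = np.array(arr, copy=True)
    absorbed = np.zeros(arr.shape[:-2])
    window = _absorber_window(grid.n, phantom.absorber_px)
    transfer_cache: dict = {}
    for kind, val in ops:
        if kind == "fs":
            h = transfer_cache.get(val)
            if h is None:
                h = grid.free_space_transfer(val).astype(out.dtype)
                transfer_cache[val] = h
            out = np.fft.ifft2(np.fft.fft2(out) * h)
        elif kind == "screen":
            out = out * np.exp(1j * phantom.screens[val]).astype(out.dtype)
        elif kind == "absorb":
            if phantom.absorber_on and phantom.absorber_px > 0:
                before = np.sum(np.abs(out) ** 2, axis=(-2, -1))
                out = out * window
                absorbed += before - np.sum(np.abs(out) ** 2, axis=(-2, -1))
    return out, absorbed


_PLANE_ORDER = {"camera": 0, "surface": 0, "target": 1}


def propagate(
    field: ComplexField,
    phantom: ScatteringPhantom,
    from_plane: str = "camera",
    to_plane: str = "target",
) -> ComplexField:
    """Propagate a field through the phantom between conjugate planes.

    ``camera``/``surface`` denote the target-conjugate plane outside the
    medium (the imaging optics are ideal); ``target`` is the internal imaging
    plane.  camera -> target applies the forward split-step chain;
    target -> camera applies the same symmetric operators in reverse order,
    which is the transpose (reciprocal) path.
    """
    if field.grid.n != phantom.grid.n:
        raise ValueError("field grid does not match phantom grid")
    for p in (from_plane, to_plane):
        if p not in _PLANE_ORDER:
            raise ValueError(f"unsupported plane {p!r}")
    a, b = _PLANE_ORDER[from_plane], _PLANE_ORDER[to_plane]
    if a == b:
        return ComplexField(field.data.copy(), field.grid, to_plane)
    out, absorbed = _apply_ops(field.data, phantom, reverse=(a > b))
    return ComplexField(out, field.grid, to_plane, absorbed_power=float(absorbed))


def reflect_stack(arr: np.ndarray, phantom: ScatteringPhantom) -> np.ndarray:
    """Double-pass reflection of a stack of fields (shape (..., n, n)).

    Propagates to the target plane, multiplies by the target reflectivity map
    and propagates back out through the same frozen screen realization along
    the transpose path, returning the camera-conjugate output fields.
    """
    down, _ = _apply_ops(arr, phantom, reverse=False)
    down = down * phantom.target_reflectivity
    up, _ = _apply_ops(down, phantom, reverse=True)
    return up


def reflect_from_target(field: ComplexField, phantom: ScatteringPhantom) -> ComplexField:
    """Double-pass reflection of a single camera-conjugate field."""
    if field.grid.n != phantom.grid.n:
        raise ValueError("field grid does not match phantom grid")
    out = reflect_stack(field.data, phantom)
    return ComplexField(out, field.grid, "camera")


# ---------------------------------------------------------------------------
# Monte-Carlo calibration check
# ---------------------------------------------------------------------------


def ballistic_transmission_mc(
    depth_smfp: float,
    n_screens: int,
    grid: GridSpec,
    n_realizations: int = 200,
    corr_length_px: float = 4.0,
    seed: int = 0,
):
    """Monte-Carlo estimate of the stack's ballistic power transmission.

    For each realization the stack's total complex transmission
    ``exp(i sum_j phi_j)`` is averaged over the grid; the ballistic power is
    the squared modulus of the ensemble-mean amplitude.  An unbiased
    estimator ``|mean|^2 - var(mean)`` is returned together with its
    delta-method standard error, for comparison with ``exp(-depth_smfp)``.
    """
    std = calibrate_screen_strength(depth_smfp, n_screens)
    rng = np.random.default_rng(seed)
    samples = np.empty(n_realizations, dtype=complex)
    for m in range(n_realizations):
        total_phase = np.zeros((grid.n, grid.n))
        for _ in range(n_screens):
            total_phase += _gaussian_phase_screen(rng, grid.n, corr_length_px, std)
        samples[m] = np.mean(np.exp(1j * total_phase))
    mean = samples.mean()
    var_mean = samples.var(ddof=1) / n_realizations
    power = float(np.abs(mean) ** 2 - var_mean)
    se = float(np.sqrt(4.0 * np.abs(mean) ** 2 * var_mean + 2.0 * var_mean ** 2))
    return power, se
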