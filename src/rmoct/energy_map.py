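"""Model energy matrix and internal-focus scoring.

The model energy matrix ``E_m = V F S V^T`` of the calibrated time-reversal
decomposition acts as a virtual camera inside the sample: the squared modulus
of its i-th column, reshaped to the scan grid, maps how the energy launched at
scan point i is distributed over the imaging plane.  Focus quality is scored
with an encircled-energy criterion: a beam counts as diffraction-limited when
a single central peak sits at the incident point and at least 80% of the map
energy falls inside the central disk — the encircled-energy test an ideal
Airy pattern passes with ~83.8% inside its first dark ring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import special

from .rm_acquisition import ScanGrid
from .time_reversal import TimeReversalDecomposition

__all__ = [
    "ModelEnergyMatrix",
    "FocusReport",
    "model_energy_matrix",
    "energy_map_at_point",
    "focus_metrics",
    "enhancement",
    "airy_pattern",
    "DEFAULT_PROBE_POINTS",
]

# Default report set of scan points (1-based on the 31 x 31 raster)
DEFAULT_PROBE_POINTS = ((6, 6), (6, 26), (16, 16), (26, 6), (26, 26))


@dataclass
class ModelEnergyMatrix:
    """``E_m = V F S V^T`` with per-scan-point map rendering."""

    matrix: np.ndarray
    scan_grid: ScanGrid
    lambda_used: float = 0.0
    depth_smfp: float | None = None

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("E_m must be square")
        if m.shape[0] != self.scan_grid.n_points:
            raise ValueError("E_m dimension must equal the number of scan points")


def model_energy_matrix(
    trd: TimeReversalDecomposition,
    filter_factors: np.ndarray,
    scan_grid: ScanGrid,
    lambda_used: float = 0.0,
    depth_smfp: float | None = None,
) -> ModelEnergyMatrix:
    """Exact triple product ``V diag(f * s) V^T`` (plain transpose)."""
    f = np.asarray(filter_factors, dtype=float)
    if f.shape != trd.s.shape:
        raise ValueError("filter factors do not match the singular spectrum")
    em = (trd.V * (f * trd.s)) @ trd.V.T
    return ModelEnergyMatrix(em, scan_grid, lambda_used=lambda_used,
                             depth_smfp=depth_smfp)


def energy_map_at_point(
    em: ModelEnergyMatrix | np.ndarray,
    scan_point: Tuple[int, int],
    scan_grid: ScanGrid | None = None,
) -> np.ndarray:
    """Internal intensity map for one scan point: |column|^2, row-major.

    The map's total equals the squared norm of the E_m column exactly;
    no per-map normalization is applied (comparisons across depths or
    before/after shaping share the acquisition scale).
    """
    if isinstance(em, ModelEnergyMatrix):
        scan_grid = em.scan_grid
        mat = em.matrix
    else:
        if scan_grid is None:
            raise ValueError("scan_grid required for a bare matrix")
        mat = np.asarray(em)
    i = scan_grid.linear_index(scan_point)
    n = scan_grid.n_side
    return np.abs(mat[:, i]).reshape(n, n) ** 2


@dataclass
class FocusReport:
    """Focus-quality metrics of one internal intensity map."""

    peak_position: Tuple[int, int]
    peak_shift: float
    central_fraction: float
    fwhm: float
    is_diffraction_limited: bool
    relative_intensity: float


def _disk_mask(shape, center, radius):
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return rr ** 2 + cc ** 2 <= radius ** 2


def _fwhm_radial(map2d: np.ndarray, peak) -> float:
    """FWHM from the azimuthally averaged radial profile about the peak,
    linearly interpolated at half maximum."""
    rr = np.arange(map2d.shape[0])[:, None] - peak[0]
    cc = np.arange(map2d.shape[1])[None, :] - peak[1]
    r = np.sqrt(rr ** 2 + cc ** 2).ravel()
    v = map2d.ravel()
    rmax = int(np.ceil(r.max()))
    half = map2d[peak] / 2.0
    prev_r, prev_v = 0.0, map2d[peak]
    for k in range(1, rmax + 1):
        ring = (r >= k - 0.5) & (r < k + 0.5)
        if not np.any(ring):
            continue
        val = v[ring].mean()
        if val <= half:
            if prev_v == val:
                r_half = float(k)
            else:
                r_half = prev_r + (prev_v - half) / (prev_v - val) * (k - prev_r)
            return 2.0 * r_half
        prev_r, prev_v = float(k), val
    return 2.0 * rmax


def focus_metrics(
    map2d: np.ndarray,
    incident_point: Tuple[int, int],
    central_radius: float = 1.5,
    reference_peak: float | None = None,
    one_based: bool = True,
) -> FocusReport:
    """Score an internal intensity map against the incident scan point.

    The peak is the argmax (ties broken by smallest row, then column); the
    central region is a disk of radius ``central_radius`` map pixels around
    the incident point (default 1.5, approximately the first Airy null of the
    unaberrated system on the scan raster); ``central_fraction`` is the
    in-disk share of the total map energy; the FWHM comes from interpolating
    the radial profile at half peak.  ``is_diffraction_limited`` requires a
    single central peak (zero shift) and >= 80% central fraction.
    """
    m = np.asarray(map2d, dtype=float)
    if np.any(m < 0):
        raise ValueError("intensity map must be non-negative")
    total = m.sum()
    if total <= 0:
        raise ValueError("degenerate (all-zero) intensity map")
    offset = 1 if one_based else 0
    inc = (incident_point[0] - offset, incident_point[1] - offset)
    if not (0 <= inc[0] < m.shape[0] and 0 <= inc[1] < m.shape[1]):
        raise ValueError("incident point outside the map")
    flat = int(np.argmax(m))  # row-major argmax = lexicographic tie-break
    peak = (flat // m.shape[1], flat % m.shape[1])
    shift = float(np.hypot(peak[0] - inc[0], peak[1] - inc[1]))
    frac = float(m[_disk_mask(m.shape, inc, central_radius)].sum() / total)
    fwhm = _fwhm_radial(m, peak)
    rel = float(m[peak] / reference_peak) if reference_peak else float(m[peak])
    return FocusReport(
        peak_position=(peak[0] + offset, peak[1] + offset),
        peak_shift=shift,
        central_fraction=frac,
        fwhm=fwhm,
        is_diffraction_limited=bool(shift < 1.0 and frac >= 0.8),
        relative_intensity=rel,
    )


def enhancement(
    map_shaped: np.ndarray,
    map_plane: np.ndarray,
    incident_point: Tuple[int, int],
    central_radius: float = 1.5,
    one_based: bool = True,
) -> float:
    """Delivered-energy ratio, shaped / unshaped, in the central disk.

    Both maps must share the acquisition normalization (unit-power inputs,
    no per-map rescaling); the ratio then measures the physical gain in
    energy delivered to the incident point.
    """
    ms = np.asarray(map_shaped, dtype=float)
    mp = np.asarray(map_plane, dtype=float)
    if ms.shape != mp.shape:
        raise ValueError("maps must share one grid")
    offset = 1 if one_based else 0
    inc = (incident_point[0] - offset, incident_point[1] - offset)
    mask = _disk_mask(ms.shape, inc, central_radius)
    denom = float(mp[mask].sum())
    if denom <= 0:
        raise ValueError("degenerate reference: zero unshaped in-disk energy")
    return float(ms[mask].sum()) / denom


def airy_pattern(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    null_radius_px: float,
) -> np.ndarray:
    """Sampled Airy intensity ``(2 J1(v)/v)^2`` with its first dark ring at
    ``null_radius_px`` pixels from ``center`` (peak normalized to 1)."""
    first_null = special.jn_zeros(1, 1)[0]  # 3.8317...
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    v = first_null * np.sqrt(rr ** 2 + cc ** 2) / null_radius_px
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = np.where(v == 0, 1.0, 2.0 * special.j1(v) / np.where(v == 0, 1.0, v))
    return amp ** 2
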