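"""Time-reversal decomposition of the reflection matrix.

The SVD ``R = U S V^dagger`` is the time-reversal decomposition: singular
states with large singular values correspond to strongly backscattering
channels (single-scattering photons in the shallow limit), while the
Marchenko-Pastur-like bulk holds the multiply scattered background.  The
regularized inversion uses Tikhonov filter factors
``f = s^2 / (s^2 + lambda^2)``, equivalent to the ridge closed form
``(R^dagger R + lambda^2 I)^{-1} R^dagger``; the regularization strength is
picked on a logarithmic grid by a deviation (normalized-residual) criterion
against paired probe measurements.  Photon classes are separated by
thresholding the singular spectrum, with energy bookkeeping on the squared
singular values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, linalg

from .rm_acquisition import ReflectionMatrix

__all__ = [
    "TimeReversalDecomposition",
    "RegularizedInverse",
    "PhotonClassification",
    "decompose",
    "tikhonov_filter",
    "regularized_invert",
    "default_lambda_grid",
    "select_lambda",
    "marchenko_pastur_threshold",
    "marchenko_pastur_cdf",
    "classify_photons",
    "open_channel_gain",
    "photon_taxonomy",
]


@dataclass
class TimeReversalDecomposition:
    """Thin SVD triplet of a reflection matrix.

    ``U`` (n_out x r) and ``V`` (n_in x r) have orthonormal columns, ``s`` is
    non-negative and decreasing, and ``R = U diag(s) V^dagger``.  The phase of
    each singular pair is fixed by making the largest-magnitude entry of each
    column of V real and positive.
    """

    U: np.ndarray
    s: np.ndarray
    V: np.ndarray

    @property
    def rank(self) -> int:
        return self.s.size

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.s) @ self.V.conj().T


def decompose(R: ReflectionMatrix | np.ndarray) -> TimeReversalDecomposition:
    """Full thin SVD of the reflection matrix with a fixed phase convention."""
    mat = R.matrix if isinstance(R, ReflectionMatrix) else np.asarray(R)
    if not np.all(np.isfinite(mat)):
        raise ValueError("matrix contains non-finite entries")
    U, s, Vh = linalg.svd(np.asarray(mat, dtype=complex), full_matrices=False,
                          lapack_driver="gesdd")
    V = Vh.conj().T
    # Phase gauge.  The per-pair phase freedom (u, v) -> (u e^{i phi}, v e^{i phi})
    # leaves R = U S V^dagger invariant but changes V S V^T, so the model energy
    # matrix is only well defined once the gauge is fixed.  We align each pair
    # with the Takagi factorization of a symmetric (reciprocal, monostatic)
    # matrix, conj(u_j) ~ v_j, via phi_j = arg(v_j^dagger conj(u_j)) / 2; for a
    # symmetric R this makes V S V^T the conjugate of R itself.  The residual
    # +- sign is anchored by the largest-magnitude entry of each V column.
    if U.shape[0] == V.shape[0]:
        z = np.einsum("ij,ij->j", V.conj(), U.conj())
        phases = np.where(np.abs(z) > 0, np.exp(0.5j * np.angle(z)), 1.0)
        V = V * phases[None, :]
        U = U * phases[None, :]
    idx = np.argmax(np.abs(V), axis=0)
    anchors = V[idx, np.arange(V.shape[1])]
    signs = np.where(
        np.abs(anchors.real) >= np.abs(anchors.imag),
        np.where(anchors.real >= 0, 1.0, -1.0),
        np.where(anchors.imag >= 0, 1.0, -1.0),
    )
    V = V * signs[None, :]
    U = U * signs[None, :]
    return TimeReversalDecomposition(U=U, s=s, V=V)


def tikhonov_filter(s: np.ndarray, lam: float) -> np.ndarray:
    """Filter factors ``f = s^2 / (s^2 + lambda^2)``.

    At ``lambda = 0`` the factors are 1 wherever ``s > 0`` (unregularized
    pseudoinverse limit) and 0 on null singular values.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    s = np.asarray(s, dtype=float)
    if lam == 0:
        return (s > 0).astype(float)
    return s ** 2 / (s ** 2 + lam ** 2)


def regularized_invert(
    trd: TimeReversalDecomposition, lam: float, e_out: np.ndarray
) -> np.ndarray:
    """Tikhonov-filtered pseudoinverse applied to an output field.

    Computes ``V F S^+ U^dagger e_out``, the filtered inverse of
    ``E_out = R E_in``; identical to the ridge estimate
    ``(R^dagger R + lambda^2 I)^{-1} R^dagger e_out``.  ``e_out`` may be a
    vector, a 2D field (flattened row-major) or a matrix of stacked columns.
    """
    e = np.asarray(e_out)
    squeeze = False
    if e.ndim == 2 and e.shape[0] != trd.U.shape[0]:
        e = e.reshape(-1)  # 2D field
    if e.ndim == 1:
        e = e[:, None]
        squeeze = True
    if e.shape[0] != trd.U.shape[0]:
        raise ValueError("output dimension does not match the decomposition")
    with np.errstate(divide="ignore", invalid="ignore"):
        if lam == 0:
            gain = np.where(trd.s > 0, 1.0 / np.where(trd.s > 0, trd.s, 1.0), 0.0)
        else:
            gain = trd.s / (trd.s ** 2 + lam ** 2)
    coeff = gain[:, None] * (trd.U.conj().T @ e)
    x = trd.V @ coeff
    return x[:, 0] if squeeze else x


def default_lambda_grid(n_points: int = 33) -> np.ndarray:
    """Logarithmically spaced regularization grid from 1e-8 to 1e8."""
    return np.logspace(-8.0, 8.0, n_points)


@dataclass
class RegularizedInverse:
    """Selected regularization state: lambda, filter factors and eta curve."""

    lam: float
    filter_factors: np.ndarray
    eta: float
    lambda_grid: np.ndarray
    eta_curve: np.ndarray


def select_lambda(
    trd: TimeReversalDecomposition,
    probe_inputs: np.ndarray,
    probe_outputs: np.ndarray,
    lambda_grid: np.ndarray | None = None,
) -> RegularizedInverse:
    """Deviation-criterion selection of the Tikhonov parameter.

    For each candidate lambda the measured probe outputs are inverted through
    the filtered operator and compared against the paired references
    (the fields that should have been delivered):
    ``eta(lambda) = ||e_est - e_ref|| / ||e_ref||`` accumulated over all
    probes.  Returns the grid minimizer (ties broken toward the smallest
    lambda) with the full eta curve retained.
    """
    cin = np.asarray(probe_inputs)
    cout = np.asarray(probe_outputs)
    if cin.ndim == 1:
        cin = cin[:, None]
    if cout.ndim == 1:
        cout = cout[:, None]
    if cin.shape[1] == 0 or cout.shape[1] == 0 or cin.shape[1] != cout.shape[1]:
        raise ValueError("probe sets must be non-empty and paired")
    ref_norm = np.linalg.norm(cin)
    if ref_norm == 0:
        raise ValueError("degenerate probe reference (all-zero norm)")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    order = np.argsort(lambda_grid)
    lambda_grid = lambda_grid[order]
    proj = trd.U.conj().T @ cout  # r x P, reused across the grid
    etas = np.empty(lambda_grid.size)
    for k, lam in enumerate(lambda_grid):
        gain = trd.s / (trd.s ** 2 + lam ** 2) if lam > 0 else np.where(
            trd.s > 0, 1.0 / np.where(trd.s > 0, trd.s, 1.0), 0.0
        )
        est = trd.V @ (gain[:, None] * proj)
        etas[k] = np.linalg.norm(est - cin) / ref_norm
    # numerically tied minima resolve toward the smallest lambda
    eta_min = float(np.min(etas))
    best = int(np.argmax(etas <= eta_min * (1 + 1e-9) + 1e-12))
    lam = float(lambda_grid[best])
    return RegularizedInverse(
        lam=lam,
        filter_factors=tikhonov_filter(trd.s, lam),
        eta=float(etas[best]),
        lambda_grid=lambda_grid,
        eta_curve=etas,
    )


# ---------------------------------------------------------------------------
# Photon classification by singular-value threshold
# ---------------------------------------------------------------------------


def _mp_support(beta: float):
    return (1.0 - np.sqrt(beta)) ** 2, (1.0 + np.sqrt(beta)) ** 2


def marchenko_pastur_cdf(x: np.ndarray, beta: float) -> np.ndarray:
    """CDF of the Marchenko-Pastur law (unit variance, aspect ratio beta<=1)."""
    a, b = _mp_support(beta)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(xs)

    def dens(t):
        num = np.sqrt(np.maximum((b - t) * (t - a), 0.0))
        return np.where(t > 0, num / (2.0 * np.pi * beta * np.where(t > 0, t, 1.0)), 0.0)

    grid = np.linspace(a, b, 2001)
    pdf = dens(grid)
    cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    out = np.interp(xs, grid, cdf, left=0.0, right=1.0)
    return out if np.ndim(x) else float(out[0])


def marchenko_pastur_threshold(
    s: np.ndarray, shape: tuple[int, int] | None = None
) -> float:
    """Random-matrix singular-value threshold from the bulk edge.

    The noise variance is estimated robustly from the median squared singular
    value against the Marchenko-Pastur median, and the threshold is placed at
    the upper bulk edge ``sqrt(sigma^2 m (1 + sqrt(beta))^2)``.  Components
    above it stand out of the fully multiply-scattered background.
    """
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty singular spectrum")
    if shape is None:
        m = n = s.size
    else:
        m, n = max(shape), min(shape)
    beta = n / m
    a, b = _mp_support(beta)
    grid = np.linspace(a, b, 2001)
    cdf = marchenko_pastur_cdf(grid, beta)
    mp_median = float(np.interp(0.5, cdf, grid))
    sigma2 = np.median(s ** 2) / (m * mp_median)
    return float(np.sqrt(sigma2 * m * b))


@dataclass
class PhotonClassification:
    """Energy split of the singular spectrum at a threshold.

    ``frac_above``/``frac_below`` are percentages of the total reflected
    energy ``sum(s^2)`` (or of the state count in ``count`` mode) carried by
    singular states above/below the threshold.
    """

    threshold: float
    frac_above: float
    frac_below: float
    n_above: int
    mode: str = "energy"

    def __post_init__(self) -> None:
        total = self.frac_above + self.frac_below
        if abs(total - 100.0) > 0.01:
            raise ValueError("photon fractions must sum to 100%")


def classify_photons(
    trd: TimeReversalDecomposition,
    threshold: float | None = None,
    mode: str = "energy",
) -> PhotonClassification:
    """Split the reflected energy at a singular-value threshold.

    Before shaping the above-threshold share is the single-scattering
    fraction; after shaping it additionally contains the multiply scattered
    photons steered into open channels.  ``threshold=None`` uses the
    Marchenko-Pastur bulk edge.  ``mode='count'`` reports state counts
    instead of energy shares.
    """
    if trd.s.size == 0:
        raise ValueError("empty singular spectrum")
    if threshold is None:
        threshold = marchenko_pastur_threshold(trd.s, (trd.U.shape[0], trd.V.shape[0]))
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    above = trd.s > threshold
    if mode == "energy":
        total = float(np.sum(trd.s ** 2))
        if total == 0:
            raise ValueError("zero-energy spectrum")
        frac_above = 100.0 * float(np.sum(trd.s[above] ** 2)) / total
    elif mode == "count":
        frac_above = 100.0 * float(np.sum(above)) / trd.s.size
    else:
        raise ValueError("mode must be 'energy' or 'count'")
    return PhotonClassification(
        threshold=float(threshold),
        frac_above=frac_above,
        frac_below=100.0 - frac_above,
        n_above=int(np.sum(above)),
        mode=mode,
    )


def open_channel_gain(
    class_before: PhotonClassification, class_after: PhotonClassification
) -> float:
    """Percentage points of reflected energy gained above threshold.

    The bookkeeping behind "x% more photons travel in open channels": the
    after-shaping above-threshold share minus the before-shaping share
    (may be negative; reported, never clamped).  Both classifications must
    use the same threshold.
    """
    if class_before.mode != class_after.mode:
        raise ValueError("classifications use different modes")
    if not np.isclose(class_before.threshold, class_after.threshold, rtol=1e-9):
        raise ValueError("classifications use different thresholds")
    return class_after.frac_above - class_before.frac_above


def photon_taxonomy(
    class_before: PhotonClassification, class_after: PhotonClassification
) -> dict:
    """Three-way photon split from the before/after classifications.

    Single-scattering photons are above threshold already before shaping;
    multiply scattered photons that reach the target plane (and can be
    steered into open channels) appear above threshold only after shaping;
    the remainder never reaches the target plane.
    """
    frac_ss = class_before.frac_above
    frac_ms1 = open_channel_gain(class_before, class_after)
    frac_ms2 = 100.0 - class_after.frac_above
    return {"frac_ss": frac_ss, "frac_ms1": frac_ms1, "frac_ms2": frac_ms2}
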