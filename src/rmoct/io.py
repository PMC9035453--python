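"""Persistence for phantoms, reflection-matrix containers and results.

The RM container is an HDF5 file holding the complex matrix, the input-ramp
descriptors and acquisition metadata, with optional groups for the SVD
(`/svd`), the regularization state (`/reg`) and matched wavefronts
(`/wavefronts`).  An NPZ fallback with the same keys is provided for
environments without HDF5.  Phase maps can be exported as 8-bit grayscale
PNGs (0..255 mapped to -pi..pi) plus lossless float TIFFs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .medium_sim import GridSpec, ScatteringPhantom
from .rm_acquisition import ReflectionMatrix, ScanGrid
from .time_reversal import RegularizedInverse, TimeReversalDecomposition
from .wavefront_opt import WavefrontSet

__all__ = [
    "save_phantom",
    "load_phantom",
    "save_rm",
    "load_rm",
    "export_phase_map",
]


def _grid_attrs(grid: GridSpec) -> dict:
    return {
        "grid_n": grid.n,
        "pitch_um": grid.pitch_um,
        "wavelength_um": grid.wavelength_um,
    }


def save_phantom(phantom: ScatteringPhantom, path) -> None:
    """Persist a phantom (screens, target map, calibration metadata)."""
    path = Path(path)
    meta = {
        "smfp_um": phantom.smfp_um,
        "depth_smfp": phantom.depth_smfp,
        "n_screens": phantom.n_screens,
        "screen_phase_std": phantom.screen_phase_std,
        "seed": phantom.seed,
        "gap_um": phantom.gap_um,
        "corr_length_px": phantom.corr_length_px,
        "absorber_px": phantom.absorber_px,
        "thickness_um": phantom.thickness_um,
        **_grid_attrs(phantom.grid),
    }
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            screens=phantom.screens,
            target_reflectivity=phantom.target_reflectivity,
            **meta,
        )
        return
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("screens", data=phantom.screens)
        fh.create_dataset("target_reflectivity", data=phantom.target_reflectivity)
        for k, v in meta.items():
            fh.attrs[k] = v


def load_phantom(path) -> ScatteringPhantom:
    path = Path(path)
    if path.suffix == ".npz":
        data = np.load(path)
        meta = {k: data[k][()] for k in data.files if k not in ("screens", "target_reflectivity")}
        screens = data["screens"]
        target = data["target_reflectivity"]
    else:
        import h5py

        with h5py.File(path, "r") as fh:
            screens = fh["screens"][...]
            target = fh["target_reflectivity"][...]
            meta = dict(fh.attrs)
    grid = GridSpec(int(meta["grid_n"]), float(meta["pitch_um"]), float(meta["wavelength_um"]))
    return ScatteringPhantom(
        grid=grid,
        smfp_um=float(meta["smfp_um"]),
        depth_smfp=float(meta["depth_smfp"]),
        n_screens=int(meta["n_screens"]),
        screen_phase_std=float(meta["screen_phase_std"]),
        screens=screens,
        target_reflectivity=target,
        seed=int(meta["seed"]),
        gap_um=float(meta["gap_um"]),
        corr_length_px=float(meta["corr_length_px"]),
        absorber_px=int(meta["absorber_px"]),
    )


def save_rm(
    rm: ReflectionMatrix,
    path,
    trd: TimeReversalDecomposition | None = None,
    reg: RegularizedInverse | None = None,
    wavefronts: WavefrontSet | None = None,
) -> None:
    """Persist an RM container with optional decomposition/regularization."""
    path = Path(path)
    attrs = {
        "depth_smfp": rm.depth_smfp,
        "phantom_seed": -1 if rm.phantom_seed is None else rm.phantom_seed,
        "snr_db": np.nan if rm.snr_db is None else rm.snr_db,
        "scan_n_side": rm.scan_grid.n_side,
        "scan_spacing_px": rm.scan_grid.spacing_px,
        "input_basis": rm.input_basis,
        **_grid_attrs(rm.grid),
    }
    if path.suffix == ".npz":
        payload = {"R": rm.matrix, **attrs}
        if trd is not None:
            payload.update({"svd_U": trd.U, "svd_S": trd.s, "svd_V": trd.V})
        if reg is not None:
            payload.update(
                {
                    "reg_lambda": reg.lam,
                    "reg_eta": reg.eta,
                    "reg_lambda_grid": reg.lambda_grid,
                    "reg_eta_curve": reg.eta_curve,
                }
            )
        if wavefronts is not None:
            payload.update(
                {
                    "wavefronts_k": wavefronts.k_columns,
                    "wavefronts_targets": np.asarray(wavefronts.targets),
                    "wavefronts_lambda": wavefronts.lambda_used,
                }
            )
        np.savez_compressed(path, **payload)
        return
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("R", data=rm.matrix)
        for k, v in attrs.items():
            fh.attrs[k] = v
        if trd is not None:
            svd = fh.create_group("svd")
            svd.create_dataset("U", data=trd.U)
            svd.create_dataset("S", data=trd.s)
            svd.create_dataset("V", data=trd.V)
        if reg is not None:
            rg = fh.create_group("reg")
            rg.attrs["lambda"] = reg.lam
            rg.attrs["eta"] = reg.eta
            rg.create_dataset("lambda_grid", data=reg.lambda_grid)
            rg.create_dataset("eta_curve", data=reg.eta_curve)
        if wavefronts is not None:
            wf = fh.create_group("wavefronts")
            wf.create_dataset("k", data=wavefronts.k_columns)
            wf.create_dataset("targets", data=np.asarray(wavefronts.targets))
            wf.attrs["lambda"] = wavefronts.lambda_used
            wf.attrs["modulation"] = wavefronts.modulation


def load_rm(path):
    """Load an RM container; returns (ReflectionMatrix, extras dict)."""
    path = Path(path)
    extras: dict = {}
    if path.suffix == ".npz":
        data = np.load(path, allow_pickle=False)
        attrs = {k: data[k][()] for k in data.files if not k.startswith(("R", "svd_", "reg_", "wavefronts_"))}
        matrix = data["R"]
        if "svd_U" in data.files:
            extras["trd"] = TimeReversalDecomposition(
                U=data["svd_U"], s=data["svd_S"], V=data["svd_V"]
            )
        if "reg_lambda" in data.files:
            extras["reg"] = RegularizedInverse(
                lam=float(data["reg_lambda"]),
                filter_factors=np.array([]),
                eta=float(data["reg_eta"]),
                lambda_grid=data["reg_lambda_grid"],
                eta_curve=data["reg_eta_curve"],
            )
    else:
        import h5py

        with h5py.File(path, "r") as fh:
            matrix = fh["R"][...]
            attrs = dict(fh.attrs)
            if "svd" in fh:
                extras["trd"] = TimeReversalDecomposition(
                    U=fh["svd/U"][...], s=fh["svd/S"][...], V=fh["svd/V"][...]
                )
            if "reg" in fh:
                extras["reg"] = RegularizedInverse(
                    lam=float(fh["reg"].attrs["lambda"]),
                    filter_factors=np.array([]),
                    eta=float(fh["reg"].attrs["eta"]),
                    lambda_grid=fh["reg/lambda_grid"][...],
                    eta_curve=fh["reg/eta_curve"][...],
                )
    grid = GridSpec(int(attrs["grid_n"]), float(attrs["pitch_um"]), float(attrs["wavelength_um"]))
    sg = ScanGrid(int(attrs["scan_n_side"]), int(attrs["scan_spacing_px"]))
    seed = int(attrs["phantom_seed"])
    snr = attrs.get("snr_db", np.nan)
    rm = ReflectionMatrix(
        matrix=matrix,
        grid=grid,
        scan_grid=sg,
        depth_smfp=float(attrs["depth_smfp"]),
        phantom_seed=None if seed < 0 else seed,
        snr_db=None if (snr is None or (isinstance(snr, float) and np.isnan(snr))) else float(snr),
        input_basis=str(attrs.get("input_basis", "focused-spot")),
    )
    return rm, extras


def export_phase_map(phase_map: np.ndarray, path, bit8: bool = True) -> None:
    """Write a phase map as 8-bit PNG (0..255 <-> -pi..pi) or float TIFF."""
    path = Path(path)
    phase = np.angle(np.exp(1j * np.asarray(phase_map, dtype=float)))
    if path.suffix.lower() == ".png":
        from PIL import Image

        scaled = np.round((phase + np.pi) / (2 * np.pi) * 255).astype(np.uint8)
        Image.fromarray(scaled, mode="L").save(path)
    else:
        import tifffile

        tifffile.imwrite(path, phase.astype(np.float32))
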