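"""Three-step wavefront-shaping protocol on synthetic phantoms.

Step 1 measures the reflection matrix with the scanning focused-spot basis,
projects it into the symmetric monostatic (scan) basis, applies the
time-reversal decomposition, selects the Tikhonov parameter with the
deviation criterion and computes the model energy matrix with per-point
focus metrics.  Step 2 inverts the calibrated RM for the matched incident
wavefronts.  Step 3 repeats the acquisition with the matched wavefronts
against the same frozen phantom, recalibrates, and compares photon classes
and delivered central-disk energy before and after shaping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import medium_sim, rm_acquisition, time_reversal, energy_map, wavefront_opt
from .energy_map import DEFAULT_PROBE_POINTS
from .medium_sim import GridSpec, ScatteringPhantom
from .rm_acquisition import ReflectionMatrix, ScanGrid

__all__ = [
    "ExperimentConfig",
    "Step1Result",
    "Step3Result",
    "run_step1",
    "run_step2",
    "run_step3",
    "run_experiment",
    "depth_survey",
]


@dataclass
class ExperimentConfig:
    """Study conditions for one simulated shaping experiment.

    Defaults realize the published protocol at desk scale: a 64 x 64 field
    grid over the 70 x 70 um field of view, a 31 x 31 scan raster (961
    inputs), five optical depths in SMFP units, a logarithmic Tikhonov grid
    spanning 1e-8..1e8, and phase-only modulation for the shaped wavefronts.
    """

    # field grid
    grid_n: int = 64
    pitch_um: float = 70.0 / 64.0
    wavelength_um: float = 0.8
    # scan raster
    scan_n_side: int = 31
    scan_spacing_px: int = 2
    aperture_radius_px: float | None = None
    # phantom
    smfp_um: float = 52.8
    depths: Tuple[float, ...] = (2.4, 4.8, 7.2, 9.6, 14.4)
    n_screens: int | None = None  # None -> two screens per SMFP
    gap_um: float = 4.0
    corr_length_px: float = 2.0
    absorber_px: int = 8
    target_map_path: str | None = None  # grayscale TIFF/PNG -> reflectivity [0,1]
    # detection
    noise_floor: float = 0.004
    # regularization / classification
    lambda_grid_points: int = 33
    n_probes: int = 96
    threshold: float | None = None  # None -> Marchenko-Pastur bulk edge
    classification_mode: str = "count"
    # shaping
    probe_points: Tuple[Tuple[int, int], ...] = DEFAULT_PROBE_POINTS
    wavefront_targets: str = "all"  # "all" | "probe"
    modulation: str = "phase_only"
    desired_output: str = "patch"
    # scoring
    central_radius: float = 1.5
    # reproducibility
    seed: int = 1

    def grid(self) -> GridSpec:
        return GridSpec(self.grid_n, self.pitch_um, self.wavelength_um)

    def scan_grid(self) -> ScanGrid:
        return ScanGrid(self.scan_n_side, self.scan_spacing_px)

    def lambda_grid(self) -> np.ndarray:
        return time_reversal.default_lambda_grid(self.lambda_grid_points)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("depths",):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "probe_points" in raw and raw["probe_points"] is not None:
            raw["probe_points"] = tuple(tuple(p) for p in raw["probe_points"])
        return cls(**raw)


def _derived_seed(*parts) -> int:
    """Deterministic sub-seed below 2**31 from a tuple of integers."""
    ss = np.random.SeedSequence([int(abs(hash(p)) % (2 ** 31)) if not isinstance(p, (int, np.integer)) else int(p) for p in parts])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class Step1Result:
    """Artifacts of the plane-wave (unshaped) acquisition at one depth."""

    config: ExperimentConfig
    depth_smfp: float
    phantom: ScatteringPhantom
    input_fields: np.ndarray
    rm_pixel: ReflectionMatrix
    rm_scan: ReflectionMatrix
    trd: time_reversal.TimeReversalDecomposition
    reg: time_reversal.RegularizedInverse
    threshold: float
    classification: time_reversal.PhotonClassification
    em: energy_map.ModelEnergyMatrix
    focus_reports: dict
    probe_indices: np.ndarray


def _load_target_map(path: str | None, grid: GridSpec) -> np.ndarray | None:
    """Load a grayscale 8/16-bit TIFF or PNG as a reflectivity map in [0, 1]."""
    if path is None:
        return None
    from PIL import Image

    img = np.asarray(Image.open(path).convert("I"), dtype=float)
    if img.shape != (grid.n, grid.n):
        raise ValueError(
            f"target map shape {img.shape} does not match the {grid.n} px grid"
        )
    peak = img.max()
    return img / peak if peak > 0 else img


def _probe_indices(config: ExperimentConfig, seed: int) -> np.ndarray:
    rng = np.random.default_rng(_derived_seed(seed, 11))
    n = config.scan_grid().n_points
    return rng.choice(n, size=min(config.n_probes, n), replace=False)


def _select_lambda_for(
    config: ExperimentConfig,
    phantom: ScatteringPhantom,
    trd: time_reversal.TimeReversalDecomposition,
    probe_fields: np.ndarray,
    probe_idx: np.ndarray,
    basis_fields: np.ndarray,
    seed_tag: int,
) -> time_reversal.RegularizedInverse:
    """Deviation-criterion calibration against re-measured probe inputs.

    A random subset of the scan inputs is measured a second time with
    independent detection noise; the filtered inverse of each measured probe
    output is compared to the pattern that should have been delivered (a
    delta at the probe's scan position).
    """
    sg = config.scan_grid()
    rm_probe = rm_acquisition.acquire_rm(
        phantom,
        probe_fields,
        sg,
        noise_floor=config.noise_floor,
        noise_seed=_derived_seed(seed_tag, 13),
    )
    b = basis_fields.reshape(len(basis_fields), -1)
    probe_outputs = b @ rm_probe.matrix
    references = np.eye(sg.n_points)[:, probe_idx]
    return time_reversal.select_lambda(
        trd, references, probe_outputs, config.lambda_grid()
    )


def run_step1(
    config: ExperimentConfig, depth_smfp: float, seed: int | None = None
) -> Step1Result:
    """Acquire, decompose and calibrate the unshaped reflection matrix."""
    seed = config.seed if seed is None else seed
    grid, sg = config.grid(), config.scan_grid()
    phantom = medium_sim.make_phantom(
        grid,
        smfp_um=config.smfp_um,
        depth_smfp=depth_smfp,
        n_screens=config.n_screens,
        target_reflectivity=_load_target_map(config.target_map_path, grid),
        seed=_derived_seed(seed, int(depth_smfp * 10), 1),
        gap_um=config.gap_um,
        corr_length_px=config.corr_length_px,
        absorber_px=config.absorber_px,
    )
    fields = rm_acquisition.ramp_input_fields(sg, grid, config.aperture_radius_px)
    rm_pixel = rm_acquisition.acquire_rm(
        phantom,
        fields,
        sg,
        noise_floor=config.noise_floor,
        noise_seed=_derived_seed(seed, int(depth_smfp * 10), 2),
    )
    rm_scan = rm_acquisition.project_to_scan_basis(rm_pixel, fields)
    trd = time_reversal.decompose(rm_scan)
    probe_idx = _probe_indices(config, seed)
    reg = _select_lambda_for(
        config, phantom, trd, fields[probe_idx], probe_idx, fields,
        _derived_seed(seed, int(depth_smfp * 10), 3),
    )
    threshold = (
        config.threshold
        if config.threshold is not None
        else time_reversal.marchenko_pastur_threshold(trd.s, rm_scan.matrix.shape)
    )
    classification = time_reversal.classify_photons(
        trd, threshold, mode=config.classification_mode
    )
    em = energy_map.model_energy_matrix(
        trd, reg.filter_factors, sg, lambda_used=reg.lam, depth_smfp=depth_smfp
    )
    reports = {
        pt: energy_map.focus_metrics(
            energy_map.energy_map_at_point(em, pt), pt, config.central_radius
        )
        for pt in config.probe_points
    }
    return Step1Result(
        config=config,
        depth_smfp=depth_smfp,
        phantom=phantom,
        input_fields=fields,
        rm_pixel=rm_pixel,
        rm_scan=rm_scan,
        trd=trd,
        reg=reg,
        threshold=threshold,
        classification=classification,
        em=em,
        focus_reports=reports,
        probe_indices=probe_idx,
    )


def run_step2(step1: Step1Result) -> wavefront_opt.WavefrontSet:
    """Invert the calibrated RM for the matched incident wavefronts."""
    cfg = step1.config
    sg = cfg.scan_grid()
    if cfg.wavefront_targets == "all":
        targets = list(sg.points())
    elif cfg.wavefront_targets == "probe":
        targets = list(cfg.probe_points)
    else:
        raise ValueError("wavefront_targets must be 'all' or 'probe'")
    return wavefront_opt.matched_wavefront_set(
        step1.trd,
        step1.reg.lam,
        targets,
        cfg.grid(),
        sg,
        depth_smfp=step1.depth_smfp,
        phantom_seed=step1.phantom.seed,
        modulation=cfg.modulation,
        desired=cfg.desired_output,
    )


@dataclass
class Step3Result:
    """Before/after comparison of the shaped re-acquisition."""

    rm_scan_shaped: ReflectionMatrix
    trd_shaped: time_reversal.TimeReversalDecomposition
    reg_shaped: time_reversal.RegularizedInverse
    classification_after: time_reversal.PhotonClassification
    open_channel_gain: float
    em_shaped: energy_map.ModelEnergyMatrix
    enhancements: dict
    pooled_enhancement: float
    focus_reports_after: dict
    taxonomy: dict


def run_step3(
    step1: Step1Result, wavefronts: wavefront_opt.WavefrontSet
) -> Step3Result:
    """Re-acquire with matched wavefronts and compare against step 1.

    Repeats the full step-1 processing on the shaped acquisition — including
    the deviation-criterion recalibration of the Tikhonov parameter — and
    reports the open-channel gain (same threshold as before shaping) and the
    central-disk delivered-energy enhancement at the probe points.
    """
    cfg = step1.config
    sg = cfg.scan_grid()
    if wavefronts.phantom_seed != step1.phantom.seed:
        raise wavefront_opt.StalenessError(
            "wavefronts do not correspond to this phantom realization"
        )
    if len(wavefronts.targets) != sg.n_points:
        raise ValueError(
            "the before/after comparison needs wavefronts for all scan points"
        )
    seed_tag = _derived_seed(step1.phantom.seed, 31)
    rm_pix_shaped = wavefront_opt.shaped_reacquire(
        step1.phantom,
        wavefronts,
        aperture_radius_px=cfg.aperture_radius_px,
        noise_floor=cfg.noise_floor,
        noise_seed=seed_tag,
    )
    rm_scan_shaped = rm_acquisition.project_to_scan_basis(
        rm_pix_shaped, step1.input_fields
    )
    trd_shaped = time_reversal.decompose(rm_scan_shaped)
    shaped_fields = wavefront_opt.shaped_input_fields(
        wavefronts, cfg.aperture_radius_px
    )
    reg_shaped = _select_lambda_for(
        cfg,
        step1.phantom,
        trd_shaped,
        shaped_fields[step1.probe_indices],
        step1.probe_indices,
        step1.input_fields,
        _derived_seed(step1.phantom.seed, 37),
    )
    classification_after = time_reversal.classify_photons(
        trd_shaped, step1.threshold, mode=cfg.classification_mode
    )
    gain = time_reversal.open_channel_gain(
        step1.classification, classification_after
    )
    em_shaped = energy_map.model_energy_matrix(
        trd_shaped,
        reg_shaped.filter_factors,
        sg,
        lambda_used=reg_shaped.lam,
        depth_smfp=step1.depth_smfp,
    )
    enhancements = {}
    num = den = 0.0
    reports_after = {}
    for pt in cfg.probe_points:
        m_plane = energy_map.energy_map_at_point(step1.em, pt)
        m_shaped = energy_map.energy_map_at_point(em_shaped, pt)
        enhancements[pt] = energy_map.enhancement(
            m_shaped, m_plane, pt, cfg.central_radius
        )
        mask = energy_map._disk_mask(
            m_plane.shape, (pt[0] - 1, pt[1] - 1), cfg.central_radius
        )
        num += m_shaped[mask].sum()
        den += m_plane[mask].sum()
        reports_after[pt] = energy_map.focus_metrics(
            m_shaped, pt, cfg.central_radius
        )
    taxonomy = time_reversal.photon_taxonomy(
        step1.classification, classification_after
    )
    return Step3Result(
        rm_scan_shaped=rm_scan_shaped,
        trd_shaped=trd_shaped,
        reg_shaped=reg_shaped,
        classification_after=classification_after,
        open_channel_gain=gain,
        em_shaped=em_shaped,
        enhancements=enhancements,
        pooled_enhancement=num / den if den > 0 else np.nan,
        focus_reports_after=reports_after,
        taxonomy=taxonomy,
    )


def run_experiment(
    config: ExperimentConfig,
    depths: Sequence[float] | None = None,
    seeds: Sequence[int] | None = None,
    shaping: bool = True,
) -> pd.DataFrame:
    """Full protocol over depths and seeds; one summary row per (depth, seed).

    Columns include the selected lambda, the before/after photon fractions
    and open-channel gain, the per-probe-point focus metrics of the unshaped
    reversal maps, and (when ``shaping``) the delivered-energy enhancement.
    """
    depths = config.depths if depths is None else depths
    seeds = (config.seed,) if seeds is None else seeds
    rows = []
    for depth in depths:
        for seed in seeds:
            s1 = run_step1(config, depth, seed)
            row = summarize_step1(s1, seed)
            if shaping:
                wfs = run_step2(s1)
                s3 = run_step3(s1, wfs)
                row.update(
                    lambda_shaped=s3.reg_shaped.lam,
                    frac_above_after=s3.classification_after.frac_above,
                    open_channel_gain=s3.open_channel_gain,
                    frac_ss=s3.taxonomy["frac_ss"],
                    frac_ms1=s3.taxonomy["frac_ms1"],
                    frac_ms2=s3.taxonomy["frac_ms2"],
                    enhancement_median=float(
                        np.median(list(s3.enhancements.values()))
                    ),
                    enhancement_pooled=s3.pooled_enhancement,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_step1(s1: Step1Result, seed: int) -> dict:
    reports = list(s1.focus_reports.values())
    return dict(
        depth_smfp=s1.depth_smfp,
        seed=seed,
        lambda_selected=s1.reg.lam,
        eta=s1.reg.eta,
        threshold=s1.threshold,
        frac_above_before=s1.classification.frac_above,
        central_fraction_median=float(
            np.median([r.central_fraction for r in reports])
        ),
        peak_intensity_median=float(
            np.median([r.relative_intensity for r in reports])
        ),
        n_shifted=int(sum(r.peak_shift >= 1 for r in reports)),
        n_diffraction_limited=int(sum(r.is_diffraction_limited for r in reports)),
    )


def depth_survey(
    config: ExperimentConfig,
    depths: Sequence[float] | None = None,
    seeds: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Unshaped reversal-map degradation versus optical depth.

    Runs step 1 only and aggregates, per depth, the seed-medians of the
    central fraction, the shifted-peak count and the peak intensity of the
    model-energy maps at the probe points (mirroring the published
    depth-series figure).
    """
    df = run_experiment(config, depths=depths, seeds=seeds, shaping=False)
    agg = (
        df.groupby("depth_smfp")
        .agg(
            central_fraction=("central_fraction_median", "median"),
            n_shifted=("n_shifted", "median"),
            peak_intensity=("peak_intensity_median", "median"),
            lambda_selected=("lambda_selected", "median"),
            frac_above=("frac_above_before", "median"),
        )
        .reset_index()
    )
    return agg
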