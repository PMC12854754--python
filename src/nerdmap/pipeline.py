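"""End-to-end workflows: per-cell analysis and nanoenvironment mapping.

Wires the stages together the way the assay is run in practice: per cell,
trajectories are split into ON/OFF by the recorded pattern mask, diffusion
coefficients and their bootstrap errors are fitted, and the obstacle
density is quantified from the pattern brightness; the pooled per-cell
points are then fitted with the inert-obstacle model, and the resulting
apparent protein radius feeds the nanoenvironment grid scan.  Every report
embeds the configuration hash and seeds so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .constants import (DARK_FRACTION, FRAME_SPACING, PERCOLATION_COVERAGE,
                        R_LIPID, T_ILL)
from .density import (BrightnessCalibration, mgfp_density, obstacle_density,
                      pattern_region_means)
from .mapping import DatasetProfile, NERDClassificationMatrix, scan_grid
from .model import (FitResult, StudyDataset, estimate_fit_error,
                    fit_apparent_radius)
from .simulate import PatternMask
from .tracking import (CellMeasurement, classify_trajectories,
                       estimate_diffusion, mobility_ratio, read_trajectories)

logger = logging.getLogger(__name__)

__all__ = ["CellInputs", "AnalysisConfig", "run_cell_analysis",
           "run_nerd_map"]


@dataclass(frozen=True)
class CellInputs:
    """Input files / precomputed values for one cell.

    The obstacle density can be supplied at three levels, in order of
    precedence: a ready ``rho_mgfp`` value, measured ``on_mean``/
    ``off_mean`` region intensities (counts/µm²), or a ``pattern_image``
    TIFF to be averaged under the same mask used for the trajectories.
    """

    cell_id: str
    trajectories: str
    mask: str
    pattern_image: str | None = None
    on_mean: float | None = None
    off_mean: float | None = None
    rho_mgfp: float | None = None


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants, calibration and per-cell inputs for one study."""

    cells: tuple
    c_p: float = PERCOLATION_COVERAGE
    r_lipid: float = R_LIPID
    dark_fraction: float = DARK_FRACTION
    oligomer_n: int = 1
    t_ill: float = T_ILL
    frame_spacing: float = FRAME_SPACING
    bulk_illumination: float = T_ILL
    calibration: BrightnessCalibration | None = None
    n_boot: int = 100
    n_sim_error: int = 1000
    rel_err_density: float = 0.0
    seed: int = 0
    label: str = ""
    grid: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("c_p", "r_lipid", "t_ill", "frame_spacing",
                     "bulk_illumination"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.cells:
            raise ValueError("config lists no cells")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cells = tuple(CellInputs(**c) for c in raw.pop("cells"))
        calib = raw.pop("calibration", None)
        if calib is not None:
            calib = BrightnessCalibration(**calib)
        return cls(cells=cells, calibration=calib, **raw)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cell_density(cell: CellInputs, mask: PatternMask,
                  config: AnalysisConfig) -> float:
    if cell.rho_mgfp is not None:
        return cell.rho_mgfp
    if cell.on_mean is not None and cell.off_mean is not None:
        on, off = cell.on_mean, cell.off_mean
    elif cell.pattern_image is not None:
        import tifffile

        img = tifffile.imread(cell.pattern_image).astype(float)
        on, off = pattern_region_means(img, mask, mask.pixel_size)
    else:
        raise ValueError(f"cell {cell.cell_id}: no density input provided")
    if config.calibration is None:
        raise ValueError("brightness calibration required to convert "
                         "region means into densities")
    return mgfp_density(on, off, config.calibration,
                        config.bulk_illumination)


def analyze_cell(cell: CellInputs, config: AnalysisConfig,
                 seed: int) -> CellMeasurement:
    """ON/OFF diffusion, mobility ratio and obstacle density for one cell."""
    trajs = read_trajectories(cell.trajectories, config.frame_spacing)
    mask = PatternMask.read(cell.mask)
    on, off, n_disc = classify_trajectories(trajs, mask)
    cell_tag = int.from_bytes(
        hashlib.sha256(cell.cell_id.encode()).digest()[:4], "big")
    rng = np.random.SeedSequence([seed, cell_tag & 0x7FFFFFFF])
    s_on, s_off = (int(s.generate_state(1)[0] & 0x7FFFFFFF)
                   for s in rng.spawn(2))
    est_on = estimate_diffusion(on, config.t_ill, n_boot=config.n_boot,
                                seed=s_on)
    est_off = estimate_diffusion(off, config.t_ill, n_boot=config.n_boot,
                                 seed=s_off)
    ratio, ratio_err = mobility_ratio(est_on, est_off)
    rho_mgfp = _cell_density(cell, mask, config)
    rho_obs = obstacle_density(rho_mgfp, config.dark_fraction,
                               config.oligomer_n)
    return CellMeasurement(
        cell_id=cell.cell_id, rho_mgfp=rho_mgfp, rho_obstacle=rho_obs,
        ratio=ratio, ratio_error=ratio_err,
        extras={"D_on": est_on.D, "D_off": est_off.D,
                "D_on_error": est_on.D_error, "D_off_error": est_off.D_error,
                "n_tracks_on": est_on.n_trajectories,
                "n_tracks_off": est_off.n_trajectories,
                "n_discarded": n_disc},
    )


def run_cell_analysis(config: AnalysisConfig):
    """Full study: per-cell analysis, radius fit and simulated fit error.

    Per-cell failures are logged and skipped (the report counts them); an
    error in the final fit aborts.  Returns
    ``(StudyDataset, FitResult, report_dict)``.
    """
    cells = []
    failures = []
    for cell in config.cells:
        try:
            cells.append(analyze_cell(cell, config, config.seed))
        except (ValueError, RuntimeError, OSError) as exc:
            logger.warning("cell %s failed: %s", cell.cell_id, exc)
            failures.append({"cell_id": cell.cell_id, "error": str(exc)})
    if not cells:
        raise RuntimeError("analysis stage: every cell failed")
    dataset = StudyDataset(cells=cells, oligomer_n=config.oligomer_n,
                           dark_fraction=config.dark_fraction,
                           label=config.label)
    fit = fit_apparent_radius(dataset, c_p=config.c_p,
                              r_lipid=config.r_lipid)
    err = estimate_fit_error(fit, dataset, n_sim=config.n_sim_error,
                             seed=config.seed,
                             rel_err_density=config.rel_err_density)
    fit = dataclasses.replace(fit, r_app_error=err)
    report = {
        "package": "nerdmap",
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "label": config.label,
        "n_cells": len(cells),
        "n_failed_cells": len(failures),
        "failures": failures,
        "r_app_nm": fit.r_app,
        "r_app_error_nm": fit.r_app_error,
        "r_poi_app_nm": fit.r_poi_app,
        "r_poi_app_error_nm": fit.r_poi_app_error,
        "r_lipid_nm": fit.r_lipid,
        "c_p": fit.c_p,
        "oligomer_n": config.oligomer_n,
        "residual_norm": fit.residual_norm,
    }
    return dataset, fit, report


def run_nerd_map(config: AnalysisConfig, fit: FitResult,
                 dataset: StudyDataset, r_poi: float,
                 seed: int | None = None) -> NERDClassificationMatrix:
    """Scan the ring-nanoenvironment grid against a fitted study.

    ``r_poi`` is the structure-derived protein core radius used to model
    the assay; the experimental comparison point is the fitted
    (r_poi_app, error).
    """
    if not fit.success:
        raise ValueError("cannot map nanoenvironments for a failed fit")
    profile = DatasetProfile.from_study(
        dataset, r_poi=r_poi, rel_err_density=config.rel_err_density,
        r_lipid=config.r_lipid, c_p=config.c_p)
    grid_kwargs = dict(config.grid)
    return scan_grid(profile, (fit.r_poi_app, fit.r_poi_app_error),
                     seed=config.seed if seed is None else seed,
                     **grid_kwargs)
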