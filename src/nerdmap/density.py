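"""Molecular counting: from pattern brightness to obstacle surface density.

The surface density of immobilized, mGFP-tagged protein in the patterned
(ON) membrane areas is obtained by dividing the background-subtracted bulk
brightness by the brightness of a single mGFP (scaled linearly to the bulk
illumination time), then correcting for the dark-chromophore fraction and
the oligomeric state n of the protein:

    ρ_obstacle = ρ_mGFP · (1 + dark_fraction) / n

With the default 20 % dark fraction the correction factor is exactly 1.2,
i.e. the dark fraction counts dark chromophores per visible one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import DARK_FRACTION

logger = logging.getLogger(__name__)

__all__ = [
    "BrightnessCalibration",
    "single_molecule_brightness",
    "mgfp_density",
    "obstacle_density",
    "reinterpret_oligomer",
    "pattern_region_means",
    "flat_field_correct",
]


@dataclass(frozen=True)
class BrightnessCalibration:
    """Single-fluorophore brightness reference.

    ``single_mgfp_brightness`` is the median integrated brightness (counts)
    of one mGFP recorded at ``calib_illumination`` seconds of illumination.
    """

    single_mgfp_brightness: float
    calib_illumination: float
    start_frame: int = 0
    n_molecules: int = 0

    def __post_init__(self):
        if self.single_mgfp_brightness <= 0:
            raise ValueError("single-molecule brightness must be > 0")
        if self.calib_illumination <= 0:
            raise ValueError("calibration illumination time must be > 0")
        if self.start_frame < 0:
            raise ValueError("start_frame must be >= 0")


def single_molecule_brightness(localizations, start_frame: int = 30,
                               calib_illumination: float = 0.020,
                               min_count: int = 20) -> BrightnessCalibration:
    """Median integrated brightness of single fluorophores.

    Only localizations at or after ``start_frame`` are used, so that
    multimeric species still present early in the photobleached movie do
    not inflate the estimate; the median makes the estimate robust to the
    remaining bright outliers.
    """
    df = localizations.data
    last = int(df["frame"].max())
    if start_frame > last:
        raise ValueError(
            f"start_frame {start_frame} is beyond the last frame {last}")
    masses = df.loc[df["frame"] >= start_frame, "mass"].to_numpy()
    if len(masses) < min_count:
        raise ValueError(
            f"only {len(masses)} localizations at/after frame {start_frame}; "
            "lower start_frame or record longer movies")
    return BrightnessCalibration(
        single_mgfp_brightness=float(np.median(masses)),
        calib_illumination=calib_illumination,
        start_frame=start_frame,
        n_molecules=len(masses),
    )


def mgfp_density(on_mean: float, off_mean: float,
                 calibration: BrightnessCalibration,
                 bulk_illumination: float) -> float:
    """Fluorophore surface density in ON areas, µm⁻².

    ``on_mean``/``off_mean`` are mean (flat-field corrected) pattern-image
    intensities per µm² in ON and OFF regions.  The OFF level is the
    diffusive background and is subtracted; the single-molecule brightness
    is scaled linearly to the bulk illumination time.
    """
    if bulk_illumination <= 0:
        raise ValueError("bulk_illumination must be > 0")
    if on_mean < off_mean:
        raise ValueError("ON mean below OFF mean: inverted pattern or "
                         "failed flat-field correction")
    scaled = (calibration.single_mgfp_brightness
              * bulk_illumination / calibration.calib_illumination)
    return (on_mean - off_mean) / scaled


def obstacle_density(rho_mgfp: float, dark_fraction: float = DARK_FRACTION,
                     n_oligomer: int = 1) -> float:
    """Correct a fluorophore density for dark tags and oligomeric state.

    The maturation correction multiplies by ``1 + dark_fraction`` (exactly
    1.2 at the default 20 % dark mGFP), then the density is divided by the
    number of tags per protein complex.
    """
    if not 0.0 <= dark_fraction < 1.0:
        raise ValueError("dark_fraction must be in [0, 1)")
    if n_oligomer < 1:
        raise ValueError("oligomer size n must be >= 1")
    if rho_mgfp < 0:
        raise ValueError("density must be >= 0")
    return rho_mgfp * (1.0 + dark_fraction) / n_oligomer


def reinterpret_oligomer(rho_obstacle: float, n_new: int) -> float:
    """Reinterpret an already-corrected obstacle density at oligomer size n.

    Pure division: a density quantified assuming monomers (1000 µm⁻²)
    becomes 500 µm⁻² when the same fluorophores are attributed to dimers.
    """
    if n_new < 1:
        raise ValueError("oligomer size n must be >= 1")
    return rho_obstacle / n_new


def pattern_region_means(image, mask, pixel_size: float):
    """Mean pattern-image intensity per µm² in ON and OFF regions.

    ``image`` must be registered to ``mask`` pixel-for-pixel and flat-field
    corrected.  Returns ``(on_mean, off_mean)`` in counts/µm².
    """
    img = np.asarray(image, dtype=float)
    if img.shape != mask.mask.shape:
        raise ValueError("image and mask shapes differ")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    area = pixel_size**2
    on = img[mask.mask]
    off = img[~mask.mask]
    if len(on) == 0 or len(off) == 0:
        raise ValueError("mask must contain both ON and OFF pixels")
    return float(on.mean() / area), float(off.mean() / area)


def flat_field_correct(image, reference):
    """Divide an image by a normalized illumination reference."""
    img = np.asarray(image, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if img.shape != ref.shape:
        raise ValueError("image and reference shapes differ")
    if np.any(ref <= 0):
        raise ValueError("reference image must be strictly positive")
    return img / (ref / ref.mean())
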