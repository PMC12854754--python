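"""Synthetic data generation and Brownian-dynamics validation oracles.

This module produces every input the analysis pipeline consumes:

* Poisson fields of immobile disc obstacles, optionally dressed with an
  annular nanoenvironment of reduced diffusivity (NERD) of width
  ``nerd_width`` in which tracer mobility is scaled by ``nerd_factor``;
* single-lipid tracer trajectories generated by off-lattice Brownian
  dynamics with reflecting obstacle cores, finite-illumination motion blur
  and Gaussian localization error, written in the same tabular schema the
  experimental tracking software emits;
* micropattern masks (circular ON dots on a square lattice);
* spanning-cluster Monte-Carlo estimates of the continuum percolation
  threshold of overlapping discs;
* noisy per-cell (density, mobility-ratio) datasets drawn from the
  ring-nanoenvironment mobility model.

Units: coordinates/box sizes in µm, radii/widths in nm, times in s,
densities in µm⁻².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .constants import FRAME_SPACING, NM2_PER_UM2, SIGMA_LOC, T_ILL

logger = logging.getLogger(__name__)

__all__ = [
    "ObstacleField",
    "SimConfig",
    "PatternMask",
    "PercolationEstimate",
    "place_obstacles",
    "simulate_tracers",
    "render_pattern_mask",
    "estimate_percolation_coverage",
    "sample_value_pairs",
    "generate_cell_dataset",
]


# --------------------------------------------------------------------------
# obstacle fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ObstacleField:
    """Immobile overlapping-disc obstacles in a periodic square box.

    Parameters
    ----------
    positions
        ``(n, 2)`` obstacle centres, µm, inside ``[0, box_size)²``.
    core_radius
        Hard (reflecting) core radius, nm.
    box_size
        Side length of the periodic box, µm.
    nerd_width
        Width of the reduced-diffusivity annulus around each core, nm.
    nerd_factor
        Tracer diffusivity inside the annulus relative to bulk, in [0, 1].
    """

    positions: np.ndarray
    core_radius: float
    box_size: float
    nerd_width: float = 0.0
    nerd_factor: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "positions", pos)
        if self.core_radius <= 0:
            raise ValueError("core_radius must be > 0")
        if self.box_size <= 0:
            raise ValueError("box_size must be > 0")
        if self.nerd_width < 0:
            raise ValueError("nerd_width must be >= 0")
        if not 0.0 <= self.nerd_factor <= 1.0:
            raise ValueError("nerd_factor must be in [0, 1]")
        if len(pos) and (pos.min() < 0 or pos.max() >= self.box_size):
            raise ValueError("obstacle positions must lie inside [0, box_size)")

    @property
    def n_obstacles(self) -> int:
        return len(self.positions)

    @property
    def density(self) -> float:
        """Number density, µm⁻²."""
        return self.n_obstacles / self.box_size**2

    @property
    def coverage(self) -> float:
        """Core area coverage 1 − exp(−ρπR²) of the overlapping discs."""
        eta = self.density * np.pi * self.core_radius**2 * NM2_PER_UM2
        return 1.0 - np.exp(-eta)


def place_obstacles(
    density: float,
    core_radius: float,
    box_size: float,
    nerd_width: float = 0.0,
    nerd_factor: float = 1.0,
    seed: int | None = None,
) -> ObstacleField:
    """Scatter immobile disc obstacles uniformly at random (Poisson field).

    The number of obstacles is Poisson with mean ``density * box_size²``;
    overlap between discs is permitted (overlapping-disc model).
    ``box_size`` must cover at least 50 core radii so that a tracer samples
    many obstacles before wrapping around the periodic box.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if core_radius <= 0:
        raise ValueError("core_radius must be > 0")
    if box_size * 1e3 < 50 * core_radius:
        raise ValueError("box_size must cover at least 50 core radii")
    rng = np.random.default_rng(seed)
    n = rng.poisson(density * box_size**2)
    positions = rng.uniform(0.0, box_size, size=(n, 2))
    return ObstacleField(
        positions=positions,
        core_radius=core_radius,
        box_size=box_size,
        nerd_width=nerd_width,
        nerd_factor=nerd_factor,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Brownian-dynamics tracer simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Time discretisation and imaging model for the tracer simulation.

    The defaults mirror the imaging protocol: 3 ms illumination followed by
    7 ms delay per 10 ms frame, 40 nm localization precision, tracer
    diffusivity of 1 µm²/s.  ``step_time`` must resolve the obstacle core:
    the rms sub-step length √(4·D·step_time) should not exceed one fifth of
    the core radius (checked by :func:`simulate_tracers`).
    """

    free_diffusion: float = 1.0       # µm²/s
    step_time: float = 1e-6           # s
    frame_spacing: float = FRAME_SPACING
    illumination_time: float = T_ILL
    localization_sigma: float = SIGMA_LOC  # µm
    boundary: str = "periodic"

    def __post_init__(self):
        if self.step_time <= 0 or self.frame_spacing <= 0:
            raise ValueError("step_time and frame_spacing must be > 0")
        if self.step_time > self.frame_spacing:
            raise ValueError("step_time must be <= frame_spacing")
        if not 0.0 <= self.illumination_time <= self.frame_spacing:
            raise ValueError("illumination_time must be in [0, frame_spacing]")
        if self.boundary != "periodic":
            raise ValueError("only periodic boundaries are supported")

    @property
    def n_steps_per_frame(self) -> int:
        return max(1, int(round(self.frame_spacing / self.step_time)))

    @property
    def n_blur_samples(self) -> int:
        """Sub-step positions averaged into one localization (motion blur)."""
        return max(1, int(round(self.illumination_time / self.step_time)))

    @property
    def step_length(self) -> float:
        """rms displacement per sub-step, µm."""
        return float(np.sqrt(4.0 * self.free_diffusion * self.step_time))

    @classmethod
    def for_field(cls, obstacle_field: ObstacleField, free_diffusion: float = 1.0,
                  **kwargs) -> "SimConfig":
        """Config whose sub-step resolves ``obstacle_field``'s core (R/5 cap)."""
        step = (obstacle_field.core_radius * 1e-3 / 5.0) ** 2 / (4.0 * free_diffusion)
        return cls(free_diffusion=free_diffusion, step_time=step, **kwargs)


@numba.njit(cache=True)
def _bd_kernel(pos0, obs, core_r, annulus_r, f_nerd, box, n_cells,
               cell_head, cell_next, sd_free, n_sub, n_blur, n_frames, seed):
    """Brownian dynamics with move-rejection at obstacle cores.

    Proposed Gaussian sub-steps that would end inside a core disc are
    rejected (the tracer stays put for that sub-step), which yields the
    correct uniform equilibrium in the accessible area for small steps.
    Sub-steps that start inside a reduced-diffusivity annulus are drawn
    with their displacement scaled by √f_nerd (local D = f·D_free).
    Coordinates are kept unwrapped; wrapping is applied only for collision
    tests against the periodic obstacle field.

    Returns blur-averaged (pre-noise) frame positions, shape (n, frames, 2).
    """
    np.random.seed(seed)
    n_tracers = pos0.shape[0]
    out = np.empty((n_tracers, n_frames, 2))
    cw = box / n_cells
    core2 = core_r * core_r
    ann2 = annulus_r * annulus_r
    has_annulus = annulus_r > core_r and f_nerd < 1.0
    sqrt_f = np.sqrt(f_nerd)
    half = 0.5 * box
    for i in range(n_tracers):
        x = pos0[i, 0]
        y = pos0[i, 1]
        # region of the current position: True if inside an annulus
        in_annulus = False
        if has_annulus:
            px = x % box
            py = y % box
            cx = int(px / cw)
            cy = int(py / cw)
            for ox in range(-1, 2):
                for oy in range(-1, 2):
                    c = ((cx + ox) % n_cells) * n_cells + (cy + oy) % n_cells
                    j = cell_head[c]
                    while j >= 0:
                        dx = px - obs[j, 0]
                        if dx > half:
                            dx -= box
                        elif dx < -half:
                            dx += box
                        dy = py - obs[j, 1]
                        if dy > half:
                            dy -= box
                        elif dy < -half:
                            dy += box
                        if dx * dx + dy * dy < ann2:
                            in_annulus = True
                        j = cell_next[j]
        for f in range(n_frames):
            bx = 0.0
            by = 0.0
            for s in range(n_sub):
                sd = sd_free
                if in_annulus:
                    sd = sd_free * sqrt_f
                nx = x + np.random.normal() * sd
                ny = y + np.random.normal() * sd
                px = nx % box
                py = ny % box
                cx = int(px / cw)
                cy = int(py / cw)
                hit_core = False
                hit_ann = False
                for ox in range(-1, 2):
                    for oy in range(-1, 2):
                        c = ((cx + ox) % n_cells) * n_cells + (cy + oy) % n_cells
                        j = cell_head[c]
                        while j >= 0:
                            dx = px - obs[j, 0]
                            if dx > half:
                                dx -= box
                            elif dx < -half:
                                dx += box
                            dy = py - obs[j, 1]
                            if dy > half:
                                dy -= box
                            elif dy < -half:
                                dy += box
                            d2 = dx * dx + dy * dy
                            if d2 < core2:
                                hit_core = True
                                break
                            if has_annulus and d2 < ann2:
                                hit_ann = True
                            j = cell_next[j]
                        if hit_core:
                            break
                    if hit_core:
                        break
                if not hit_core:
                    x = nx
                    y = ny
                    in_annulus = hit_ann
                if s < n_blur:
                    bx += x
                    by += y
            out[i, f, 0] = bx / n_blur
            out[i, f, 1] = by / n_blur
    return out


def _obstacle_grid(field: ObstacleField, cell_width_min: float):
    """Linked-cell neighbour lists for the periodic obstacle field."""
    n_cells = max(3, int(field.box_size / cell_width_min))
    head = -np.ones(n_cells * n_cells, dtype=np.int64)
    nxt = -np.ones(max(1, field.n_obstacles), dtype=np.int64)
    cw = field.box_size / n_cells
    for j in range(field.n_obstacles):
        c = int(field.positions[j, 0] / cw) * n_cells + int(field.positions[j, 1] / cw)
        nxt[j] = head[c]
        head[c] = j
    return n_cells, head, nxt


def _seed_positions(field: ObstacleField, n_tracers: int, rng) -> np.ndarray:
    """Uniform tracer starting points in the accessible (non-core) area."""
    if field.n_obstacles == 0:
        return rng.uniform(0.0, field.box_size, size=(n_tracers, 2))
    tree = cKDTree(field.positions, boxsize=field.box_size)
    r_um = field.core_radius * 1e-3
    out = np.empty((n_tracers, 2))
    k = 0
    for _ in range(1000):
        cand = rng.uniform(0.0, field.box_size, size=(max(64, n_tracers), 2))
        dist, _ = tree.query(cand)
        good = cand[dist > r_um]
        take = min(len(good), n_tracers - k)
        out[k:k + take] = good[:take]
        k += take
        if k == n_tracers:
            return out
    raise RuntimeError("could not seed tracers outside obstacle cores; "
                       "accessible area is too small")


def simulate_tracers(
    obstacle_field: ObstacleField,
    config: SimConfig,
    n_tracers: int,
    n_frames: int,
    seed: int | None = None,
    brightness: float = 500.0,
):
    """Simulate single-lipid tracer trajectories through an obstacle field.

    Tracers perform Gaussian sub-steps with local diffusivity
    ``config.free_diffusion`` (scaled by ``nerd_factor`` inside annuli);
    moves ending inside a hard core are rejected.  The reported position of
    each frame is the average of the sub-step positions during the
    illumination window (motion blur) plus Gaussian localization noise.

    Returns a :class:`~nerdmap.tracking.TrajectorySet` in the standard
    tabular schema (track_id, frame, x_um, y_um, mass), with coordinates
    unwrapped (not folded back into the periodic box).
    """
    from .tracking import TrajectorySet

    if n_tracers <= 0 or n_frames <= 0:
        return TrajectorySet(
            data=pd.DataFrame(
                {"track_id": pd.Series(dtype=int), "frame": pd.Series(dtype=int),
                 "x_um": pd.Series(dtype=float), "y_um": pd.Series(dtype=float),
                 "mass": pd.Series(dtype=float)}),
            frame_spacing=config.frame_spacing,
        )
    r_um = obstacle_field.core_radius * 1e-3
    if config.step_length > r_um / 5 and obstacle_field.n_obstacles > 0:
        warnings.warn(
            f"sub-step length {config.step_length * 1e3:.2f} nm exceeds "
            f"core_radius/5 = {obstacle_field.core_radius / 5:.2f} nm; "
            "obstacle collisions are under-resolved",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    pos0 = _seed_positions(obstacle_field, n_tracers, rng)
    ann_um = (obstacle_field.core_radius + obstacle_field.nerd_width) * 1e-3
    n_cells, head, nxt = _obstacle_grid(obstacle_field, max(3 * ann_um, 1e-9))
    sd = np.sqrt(2.0 * config.free_diffusion * config.step_time)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    frames = _bd_kernel(
        pos0, obstacle_field.positions, r_um, ann_um,
        obstacle_field.nerd_factor, obstacle_field.box_size, n_cells,
        head, nxt, sd, config.n_steps_per_frame, config.n_blur_samples,
        n_frames, kernel_seed,
    )
    if config.localization_sigma > 0:
        frames = frames + rng.normal(0.0, config.localization_sigma, frames.shape)
    n = n_tracers * n_frames
    df = pd.DataFrame({
        "track_id": np.repeat(np.arange(n_tracers), n_frames),
        "frame": np.tile(np.arange(n_frames), n_tracers),
        "x_um": frames[:, :, 0].ravel(),
        "y_um": frames[:, :, 1].ravel(),
        "mass": np.full(n, float(brightness)),
    })
    return TrajectorySet(data=df, frame_spacing=config.frame_spacing)


# --------------------------------------------------------------------------
# micropattern masks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternMask:
    """Boolean raster of the micropattern (True = ON area).

    ``mask[i, j]`` covers the pixel with x ∈ [i·p, (i+1)·p) and
    y ∈ [j·p, (j+1)·p) for pixel size p.
    """

    mask: np.ndarray
    pixel_size: float   # µm
    dot_diameter: float  # µm
    pitch: float        # µm

    @property
    def extent(self) -> tuple[float, float]:
        return (self.mask.shape[0] * self.pixel_size,
                self.mask.shape[1] * self.pixel_size)

    @property
    def on_fraction(self) -> float:
        return float(self.mask.mean())

    def lookup(self, x, y):
        """Classify points: returns (is_on, inside) boolean arrays.

        ``inside`` is False for points outside the raster extent; their
        ``is_on`` value is meaningless and must be ignored.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor(x / self.pixel_size).astype(int)
        iy = np.floor(y / self.pixel_size).astype(int)
        inside = ((ix >= 0) & (ix < self.mask.shape[0])
                  & (iy >= 0) & (iy < self.mask.shape[1]))
        on = np.zeros(x.shape, dtype=bool)
        on[inside] = self.mask[ix[inside], iy[inside]]
        return on, inside

    def write(self, tiff_path, sidecar_path=None):
        """Write the raster as single-channel TIFF plus a JSON sidecar."""
        import json
        import tifffile

        tifffile.imwrite(str(tiff_path), self.mask.astype(np.uint8))
        if sidecar_path is None:
            sidecar_path = str(tiff_path) + ".json"
        with open(sidecar_path, "w") as fh:
            json.dump({"pixel_size_um": self.pixel_size,
                       "dot_diameter_um": self.dot_diameter,
                       "pitch_um": self.pitch}, fh, indent=1)

    @classmethod
    def read(cls, tiff_path, sidecar_path=None):
        import json
        import tifffile

        if sidecar_path is None:
            sidecar_path = str(tiff_path) + ".json"
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        mask = tifffile.imread(str(tiff_path)).astype(bool)
        return cls(mask=mask, pixel_size=meta["pixel_size_um"],
                   dot_diameter=meta["dot_diameter_um"], pitch=meta["pitch_um"])


def render_pattern_mask(
    dot_diameter: float = 3.0,
    pitch: float = 6.0,
    pixel_size: float = 0.05,
    extent: float = 18.0,
) -> PatternMask:
    """Rasterize circular ON dots on a square lattice.

    Dot centres sit at ((i + ½)·pitch, (j + ½)·pitch).  A pixel is ON if its
    centre lies within a dot.  ``pixel_size`` must be at most a quarter of
    the dot diameter so the dots are adequately sampled.
    """
    if dot_diameter < 0 or pitch <= 0 or pixel_size <= 0 or extent <= 0:
        raise ValueError("geometry parameters must be positive")
    n = max(1, int(round(extent / pixel_size)))
    if dot_diameter == 0:
        return PatternMask(np.zeros((n, n), dtype=bool), pixel_size, 0.0, pitch)
    if dot_diameter >= pitch:
        raise ValueError("dot_diameter must be smaller than pitch")
    if pixel_size > dot_diameter / 4:
        raise ValueError("pixel_size must be <= dot_diameter/4 (undersampled)")
    centers = (np.arange(n) + 0.5) * pixel_size
    # distance of each pixel centre to the nearest lattice dot centre
    dx = (centers - pitch / 2) % pitch
    dx = np.minimum(dx, pitch - dx)
    d2 = dx[:, None] ** 2 + dx[None, :] ** 2
    mask = d2 <= (dot_diameter / 2) ** 2
    return PatternMask(mask, pixel_size, dot_diameter, pitch)


# --------------------------------------------------------------------------
# percolation threshold
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PercolationEstimate:
    """Critical area coverage of overlapping discs, with standard error."""

    coverage: float
    se: float
    core_radius: float
    box_size: float
    n_reps: int
    evaluations: tuple = field(default=(), repr=False)


def _spanning_replicate(rng, density, core_um, box, rule):
    """One disc configuration; True if a cluster spans the box."""
    n = rng.poisson(density * box * box)
    if n == 0:
        return False
    pos = rng.uniform(0.0, box, size=(n, 2))
    tree = cKDTree(pos)
    pairs = tree.query_pairs(2 * core_um, output_type="ndarray")
    if len(pairs):
        g = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                       shape=(n, n))
        _, labels = connected_components(g, directed=False)
    else:
        labels = np.arange(n)
    x, y = pos[:, 0], pos[:, 1]
    left = np.unique(labels[x < core_um])
    right = np.unique(labels[x > box - core_um])
    lr = len(np.intersect1d(left, right, assume_unique=True)) > 0
    if rule == "single":
        return lr
    top = np.unique(labels[y < core_um])
    bottom = np.unique(labels[y > box - core_um])
    tb = len(np.intersect1d(top, bottom, assume_unique=True)) > 0
    return lr or tb


def spanning_probability(coverage, core_radius, box_size, n_reps, seed=None,
                         rule="single"):
    """Monte-Carlo spanning probability at a given core area coverage."""
    core_um = core_radius * 1e-3
    eta = -np.log(1.0 - coverage)
    density = eta / (np.pi * core_um**2)
    rng = np.random.default_rng(seed)
    hits = sum(_spanning_replicate(rng, density, core_um, box_size, rule)
               for _ in range(n_reps))
    return hits / n_reps


def estimate_percolation_coverage(
    core_radius: float,
    box_size: float,
    n_reps: int = 200,
    seed: int | None = None,
    rule: str = "single",
    bracket: tuple[float, float] = (0.55, 0.78),
    n_bisect: int = 10,
) -> PercolationEstimate:
    """Estimate the critical coverage of overlapping discs by bisection.

    Discs of ``core_radius`` are Poisson-placed; the overlap graph is built
    with union-find and a replicate percolates if one cluster connects the
    left and right box edges (``rule="single"``; ``rule="either"`` also
    accepts top-bottom spanning).  The obstacle density is bisected to the
    50 % spanning probability and the area coverage 1 − exp(−ρπR²) there is
    returned.  The quoted SE combines the binomial uncertainty of the final
    probability estimate (mapped through the local slope of the spanning
    curve) with the residual bisection bracket.

    ``box_size`` must be at least 100 core radii; smaller boxes carry a
    finite-size bias larger than the statistical error.
    """
    if box_size * 1e3 < 100 * core_radius:
        raise ValueError("box_size must be >= 100 core radii "
                         "(finite-size bias)")
    if n_reps < 20:
        raise ValueError("n_reps too small for a meaningful estimate")
    rng = np.random.default_rng(seed)
    lo, hi = bracket
    evals = []
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        sub = int(rng.integers(0, 2**31 - 1))
        p = spanning_probability(mid, core_radius, box_size, n_reps, sub, rule)
        evals.append((mid, p))
        if p < 0.5:
            lo = mid
        else:
            hi = mid
    coverage = 0.5 * (lo + hi)
    # local slope of the spanning curve: weighted linear fit over the
    # transition-region evaluations (bisection concentrates them there)
    pts = np.array([(c, p) for c, p in evals if 0.02 < p < 0.98])
    if len(pts) >= 3 and np.ptp(pts[:, 0]) > 1e-6:
        slope = abs(np.polyfit(pts[:, 0], pts[:, 1], 1)[0])
    else:
        slope = 20.0  # conservative fallback for the finite-size window
    slope = max(slope, 5.0)
    se_binom = np.sqrt(0.25 / n_reps) / slope
    se = float(np.hypot(se_binom, 0.5 * (hi - lo)))
    return PercolationEstimate(
        coverage=float(coverage), se=se, core_radius=core_radius,
        box_size=box_size, n_reps=n_reps, evaluations=tuple(evals),
    )


# --------------------------------------------------------------------------
# per-cell study datasets
# --------------------------------------------------------------------------

def _as_sampler(density_sampler):
    """Normalise a density specification to a callable(rng, size)."""
    if callable(density_sampler):
        return density_sampler
    if hasattr(density_sampler, "rvs"):
        return lambda rng, size: density_sampler.rvs(size=size, random_state=rng)
    arr = np.asarray(density_sampler, dtype=float)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValueError("empirical density sample must be a non-empty 1D array")
    return lambda rng, size: rng.choice(arr, size=size, replace=True)


def sample_value_pairs(
    params,
    density_sampler,
    rel_err_density: float,
    rel_err_ratio: float,
    n: int,
    rng,
    ratio_clip: float = 1.05,
    max_retries: int = 100,
):
    """Draw noisy (ρ_obstacle, D_ON/D_OFF) value pairs from the ring model.

    For each pair a true density is drawn, the true mobility ratio is
    computed from the nanoenvironment model, and observed density and ratio
    are drawn from Gaussians centred on the truths with the given relative
    SDs.  Ratios are clipped to (0, ratio_clip]; negative draws are
    redrawn (bounded retries).

    Returns ``(rho_true, rho_obs, ratio_obs, n_clipped)``.
    """
    from .model import nerd_mobility_ratio

    if rel_err_density < 0 or rel_err_ratio < 0:
        raise ValueError("relative errors must be >= 0")
    sampler = _as_sampler(density_sampler)
    rho_true = np.asarray(sampler(rng, n), dtype=float)
    for _ in range(max_retries):
        bad = ~(rho_true >= 0)
        if not bad.any():
            break
        rho_true[bad] = sampler(rng, int(bad.sum()))
    else:
        raise RuntimeError("density sampler kept yielding negative values")
    ratio_true = nerd_mobility_ratio(params, rho_true)
    ratio_obs = ratio_true * (1.0 + rel_err_ratio * rng.standard_normal(n))
    rho_obs = rho_true * (1.0 + rel_err_density * rng.standard_normal(n))
    for _ in range(max_retries):
        bad = rho_obs < 0
        if not bad.any():
            break
        rho_obs[bad] = rho_true[bad] * (
            1.0 + rel_err_density * rng.standard_normal(int(bad.sum())))
    else:
        rho_obs = np.abs(rho_obs)
    n_clipped = int(np.sum((ratio_obs > ratio_clip) | (ratio_obs <= 0)))
    ratio_obs = np.clip(ratio_obs, 1e-6, ratio_clip)
    return rho_true, rho_obs, ratio_obs, n_clipped


def generate_cell_dataset(
    params,
    density_sampler,
    rel_err_density: float,
    rel_err_ratio: float,
    n_cells: int,
    seed: int | None = None,
    label: str = "synthetic",
):
    """Generate a noisy per-cell study dataset from the ring model.

    Emulates a patterned-cell experiment: each cell contributes one
    (obstacle density, D_ON/D_OFF) pair with multiplicative Gaussian
    measurement noise of the stated relative SDs.  The per-cell
    ``ratio_error`` is recorded as ``rel_err_ratio`` times the observed
    ratio, as an experimenter would estimate it.
    """
    from .model import StudyDataset
    from .tracking import CellMeasurement

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    _, rho_obs, ratio_obs, n_clipped = sample_value_pairs(
        params, density_sampler, rel_err_density, rel_err_ratio, n_cells, rng)
    if n_clipped:
        logger.info("generate_cell_dataset: clipped %d mobility ratios",
                    n_clipped)
    cells = [
        CellMeasurement(
            cell_id=f"sim-{i:04d}",
            rho_mgfp=rho_obs[i] / 1.2,
            rho_obstacle=rho_obs[i],
            ratio=ratio_obs[i],
            ratio_error=rel_err_ratio * ratio_obs[i],
        )
        for i in range(n_cells)
    ]
    return StudyDataset(cells=cells, label=label)
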