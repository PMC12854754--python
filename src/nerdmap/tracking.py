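"""Single-molecule trajectory handling, MSD analysis and diffusion fitting.

Turns per-cell trajectory tables plus a micropattern mask into diffusion
coefficients for the protein-enriched (ON) and depleted (OFF) membrane
areas.  The estimator chain is the standard single-particle-tracking one:
pooled time-and-ensemble MSD, a short-lag linear fit with motion-blur
correction,

    MSD(t_lag) = 4·D·(t_lag − t_ill/3) + 4·σ²,

and trajectory-level bootstrap errors.  Fitting only the first two lag
points avoids the apparent subdiffusion that the selection mask induces at
long lags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectorySet",
    "MSDCurve",
    "DiffusionEstimate",
    "CellMeasurement",
    "read_trajectories",
    "classify_trajectories",
    "compute_msd",
    "fit_diffusion",
    "bootstrap_diffusion",
    "estimate_diffusion",
    "mobility_ratio",
]

_COLUMNS = ["track_id", "frame", "x_um", "y_um", "mass"]


@dataclass(frozen=True)
class TrajectorySet:
    """Time-ordered single-molecule localizations grouped by track.

    ``data`` holds one row per localization with columns
    ``track_id, frame, x_um, y_um, mass``; rows are sorted by
    (track_id, frame) and frames are unique within a track.  Frame gaps are
    allowed and contribute only to the lags they span.
    """

    data: pd.DataFrame
    frame_spacing: float  # s

    def __post_init__(self):
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be > 0")
        df = self.data
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing trajectory columns: {missing}")
        df = df[_COLUMNS].copy()
        df["track_id"] = df["track_id"].astype(np.int64)
        df["frame"] = df["frame"].astype(np.int64)
        df = df.sort_values(["track_id", "frame"], kind="stable",
                            ignore_index=True)
        dup = df.duplicated(["track_id", "frame"])
        if dup.any():
            bad = sorted(int(t) for t in df.loc[dup, "track_id"].unique())
            raise ValueError(
                f"duplicate (track_id, frame) rows in tracks {bad[:10]}")
        if not np.isfinite(df[["x_um", "y_um"]].to_numpy()).all():
            raise ValueError("non-finite coordinates in trajectory table")
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    def subset(self, track_ids) -> "TrajectorySet":
        mask = self.data["track_id"].isin(np.asarray(track_ids))
        return replace(self, data=self.data[mask].reset_index(drop=True))

    def write(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_trajectories(path, frame_spacing: float) -> TrajectorySet:
    """Read a trajectory table (CSV or tab-separated) and validate it.

    Malformed (non-numeric / incomplete) rows are dropped and counted;
    missing columns or an empty file raise.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"empty trajectory file: {path}")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    n_raw = len(df)
    df = df[_COLUMNS].apply(pd.to_numeric, errors="coerce").dropna()
    if len(df) < n_raw:
        logger.warning("%s: dropped %d malformed rows", path, n_raw - len(df))
    if df.empty:
        raise ValueError(f"{path}: no valid trajectory rows")
    return TrajectorySet(data=df, frame_spacing=frame_spacing)


def classify_trajectories(trajectories: TrajectorySet, mask,
                          rule: str = "whole"):
    """Split trajectories into ON and OFF groups using a pattern mask.

    With the default whole-trajectory rule, a track is ON if every
    localization falls on ON pixels, OFF if every localization falls on OFF
    pixels; tracks that straddle a dot edge are discarded and counted.
    Tracks with any localization outside the mask extent are discarded with
    a warning.  ``rule="segment"`` instead cuts each track into maximal
    same-region runs (minimum length 2) and relabels them as new tracks.

    Returns ``(on, off, n_discarded)``.
    """
    df = trajectories.data
    on_pt, inside = mask.lookup(df["x_um"].to_numpy(), df["y_um"].to_numpy())
    if rule == "whole":
        grp_on = pd.Series(on_pt).groupby(df["track_id"].to_numpy())
        grp_in = pd.Series(inside).groupby(df["track_id"].to_numpy())
        all_on = grp_on.all()
        any_on = grp_on.any()
        all_in = grp_in.all()
        n_out = int((~all_in).sum())
        if n_out:
            logger.warning("classify_trajectories: %d tracks extend outside "
                           "the mask extent; discarded", n_out)
        on_ids = all_on.index[all_on & all_in]
        off_ids = any_on.index[~any_on & all_in]
        n_disc = trajectories.n_tracks - len(on_ids) - len(off_ids)
        return (trajectories.subset(on_ids), trajectories.subset(off_ids),
                int(n_disc))
    if rule != "segment":
        raise ValueError("rule must be 'whole' or 'segment'")
    # per-localization segmentation: contiguous same-status runs, length >= 2
    status = np.where(inside, on_pt.astype(int), -1)
    tid = df["track_id"].to_numpy()
    new_seg = np.ones(len(df), dtype=bool)
    new_seg[1:] = (tid[1:] != tid[:-1]) | (status[1:] != status[:-1])
    seg_id = np.cumsum(new_seg) - 1
    seg = df.assign(_seg=seg_id, _status=status)
    sizes = seg.groupby("_seg")["_seg"].transform("size")
    keep = (sizes >= 2) & (status >= 0)
    kept = seg[keep]
    n_disc = int(seg.loc[~keep, "_seg"].nunique())
    parts = {}
    for label, code in (("on", 1), ("off", 0)):
        sub = kept[kept["_status"] == code]
        sub = sub.assign(track_id=sub["_seg"])[_COLUMNS]
        parts[label] = replace(trajectories,
                               data=sub.reset_index(drop=True))
    return parts["on"], parts["off"], n_disc


@dataclass(frozen=True)
class MSDCurve:
    """Pooled mean square displacement versus lag time."""

    lag_times: np.ndarray  # s, increasing
    msd: np.ndarray        # µm²
    n_pairs: np.ndarray    # displacement pairs per lag
    frame_spacing: float = 0.0

    def __post_init__(self):
        lt = np.asarray(self.lag_times, dtype=float)
        if len(lt) == 0 or np.any(lt <= 0) or np.any(np.diff(lt) <= 0):
            raise ValueError("lag_times must be positive and increasing")
        object.__setattr__(self, "lag_times", lt)
        object.__setattr__(self, "msd", np.asarray(self.msd, dtype=float))
        object.__setattr__(self, "n_pairs",
                           np.asarray(self.n_pairs, dtype=np.int64))


def _per_track_lag_sums(df: pd.DataFrame, max_lag: int):
    """Sum of squared displacements and pair counts per (track, lag).

    Returns two (n_tracks, max_lag) arrays aligned with the unique sorted
    track ids.  This is the bootstrap workhorse: resampling tracks is a
    weighted sum over rows.
    """
    tids = df["track_id"].to_numpy()
    track_index = {t: i for i, t in enumerate(pd.unique(tids))}
    n_tracks = len(track_index)
    sums = np.zeros((n_tracks, max_lag))
    counts = np.zeros((n_tracks, max_lag), dtype=np.int64)
    key = pd.MultiIndex.from_arrays([tids, df["frame"].to_numpy()])
    xy = df[["x_um", "y_um"]].to_numpy()
    frame = df["frame"].to_numpy()
    base = pd.Series(np.arange(len(df)), index=key)
    for lag in range(1, max_lag + 1):
        target = pd.MultiIndex.from_arrays([tids, frame + lag])
        j = base.reindex(target).to_numpy()
        ok = ~np.isnan(j)
        if not ok.any():
            continue
        i_idx = np.flatnonzero(ok)
        j_idx = j[ok].astype(np.int64)
        d = xy[j_idx] - xy[i_idx]
        sq = np.einsum("ij,ij->i", d, d)
        rows = np.fromiter((track_index[t] for t in tids[i_idx]),
                           dtype=np.int64, count=len(i_idx))
        np.add.at(sums[:, lag - 1], rows, sq)
        np.add.at(counts[:, lag - 1], rows, 1)
    return sums, counts


def compute_msd(trajectories: TrajectorySet, max_lag: int) -> MSDCurve:
    """Pooled time-and-ensemble MSD over all overlapping displacement pairs.

    For each lag ℓ the mean of |r(t+ℓ) − r(t)|² is taken over every pair of
    localizations ℓ frames apart, across all tracks.  Lags beyond the
    longest track are truncated (logged).
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if len(trajectories) == 0:
        raise ValueError("empty trajectory set")
    sums, counts = _per_track_lag_sums(trajectories.data, max_lag)
    tot = sums.sum(axis=0)
    n = counts.sum(axis=0)
    valid = n > 0
    if not valid[0]:
        raise ValueError("no displacement pairs at lag 1")
    last = int(np.max(np.flatnonzero(valid))) + 1
    if last < max_lag:
        logger.info("compute_msd: truncated at lag %d (requested %d)",
                    last, max_lag)
    lags = np.arange(1, last + 1)
    n = n[:last]
    msd = np.divide(tot[:last], n, out=np.zeros(last), where=n > 0)
    return MSDCurve(lag_times=lags * trajectories.frame_spacing, msd=msd,
                    n_pairs=n, frame_spacing=trajectories.frame_spacing)


@dataclass(frozen=True)
class DiffusionEstimate:
    """Diffusion coefficient and localization precision from the MSD fit."""

    D: float                 # µm²/s
    sigma_loc: float         # µm
    D_error: float = float("nan")  # bootstrap SD, µm²/s
    n_trajectories: int = 0
    negative_intercept: bool = False

    @property
    def valid(self) -> bool:
        return np.isfinite(self.D) and self.D >= 0


def fit_diffusion(curve: MSDCurve, t_ill: float,
                  n_points: int = 2) -> DiffusionEstimate:
    """Fit the blur-corrected linear MSD model to the first lags.

    Least squares of MSD against (t_lag − t_ill/3) over the first
    ``n_points`` lags; slope/4 is D and intercept/4 is σ².  With
    ``n_points=2`` this is the exact two-point solution.  A negative
    intercept is truncated to σ = 0 and flagged.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if len(curve.lag_times) < n_points:
        raise ValueError(f"MSD curve has fewer than {n_points} lags")
    x = curve.lag_times[:n_points] - t_ill / 3.0
    y = curve.msd[:n_points]
    slope, intercept = np.polyfit(x, y, 1)
    neg = intercept < 0
    sigma = 0.0 if neg else float(np.sqrt(intercept / 4.0))
    return DiffusionEstimate(D=float(slope / 4.0), sigma_loc=sigma,
                             negative_intercept=bool(neg))


def bootstrap_diffusion(trajectories: TrajectorySet, t_ill: float,
                        n_boot: int = 100, seed: int | None = None,
                        n_points: int = 2) -> float:
    """Bootstrap SD of the fitted D, resampling whole trajectories.

    Trajectories are the resampling unit.  Resamples without any lag-1 or
    lag-``n_points`` pairs are skipped and counted.
    """
    if trajectories.n_tracks < 5:
        raise ValueError("need at least 5 trajectories to bootstrap")
    rng = np.random.default_rng(seed)
    sums, counts = _per_track_lag_sums(trajectories.data, n_points)
    n_tracks = sums.shape[0]
    t_lag = (np.arange(1, n_points + 1) * trajectories.frame_spacing
             - t_ill / 3.0)
    ds = []
    skipped = 0
    for _ in range(n_boot):
        w = np.bincount(rng.integers(0, n_tracks, n_tracks),
                        minlength=n_tracks).astype(float)
        n = w @ counts
        if np.any(n == 0):
            skipped += 1
            continue
        msd = (w @ sums) / n
        slope, _ = np.polyfit(t_lag, msd, 1)
        ds.append(slope / 4.0)
    if skipped:
        logger.info("bootstrap_diffusion: skipped %d degenerate resamples",
                    skipped)
    if len(ds) < 2:
        raise RuntimeError("bootstrap failed: almost all resamples degenerate")
    return float(np.std(ds, ddof=0))


def estimate_diffusion(trajectories: TrajectorySet, t_ill: float,
                       n_boot: int = 100, seed: int | None = None,
                       n_points: int = 2) -> DiffusionEstimate:
    """Convenience: pooled MSD fit plus bootstrap error in one call."""
    curve = compute_msd(trajectories, max_lag=n_points)
    est = fit_diffusion(curve, t_ill, n_points=n_points)
    err = bootstrap_diffusion(trajectories, t_ill, n_boot=n_boot, seed=seed,
                              n_points=n_points)
    return replace(est, D_error=err, n_trajectories=trajectories.n_tracks)


def mobility_ratio(on: DiffusionEstimate, off: DiffusionEstimate):
    """D_ON/D_OFF with first-order (delta-method) error propagation."""
    if not np.isfinite(off.D) or off.D <= 0:
        raise ValueError("OFF diffusion coefficient must be > 0")
    ratio = on.D / off.D
    e_on = 0.0 if not np.isfinite(on.D_error) else on.D_error
    e_off = 0.0 if not np.isfinite(off.D_error) else off.D_error
    err = np.sqrt((e_on / off.D) ** 2 + (on.D * e_off / off.D**2) ** 2)
    return float(ratio), float(err)


@dataclass(frozen=True)
class CellMeasurement:
    """Per-cell observables: obstacle density and tracer mobility ratio."""

    cell_id: str
    rho_mgfp: float       # fluorophore density in ON areas, µm⁻²
    rho_obstacle: float   # maturation/oligomer-corrected obstacle density, µm⁻²
    ratio: float          # D_ON / D_OFF
    ratio_error: float = float("nan")
    extras: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.rho_mgfp < 0 or self.rho_obstacle < 0:
            raise ValueError("densities must be >= 0")
        if not self.ratio > 0:
            raise ValueError("mobility ratio must be > 0")
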