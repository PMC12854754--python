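# Methods

This note documents the models, estimators, defaults and numerical choices
behind `nerdmap`, and what the synthetic-data tests do and do not show
about real data.

## Physical picture and units

A membrane protein of in-plane radius `R_POI` (nm) is immobilized at
surface density `ρ` (µm⁻²) inside micropatterned ON areas; a lipid tracer
of radius `R_lipid` diffuses with coefficient `D` (µm²/s).  The package
convention is radii/widths in nm, coordinates and box sizes in µm, times
in s.  The single nm²→µm² conversion (10⁻⁶) lives in one helper
(`model._area_exponent`), so the model formulas read exactly as published.

## Obstacle mobility model

For randomly placed, overlapping, immobile discs the mobility ratio is

    D_ON/D_OFF = 1 − √(1 − exp(−ρπR²/C_P)),        R = R_POI + R_lipid

with `C_P = 0.676`, the critical area coverage of overlapping discs at the
2D continuum percolation threshold (size-independent).  The formula is an
empirical calibration of tracer simulations at experimental time scales,
not a first-principles transport law; see *Limitations*.

A ring nanoenvironment of width `d_NERD` in which tracer mobility is
scaled by `f_NERD ∈ [0, 1]` multiplies this core term by

    B = 1 − (1 − e^(−ρπx))(1 − f) + (e^(−2ρπx) − e^(−ρπx))(1 − f)²,
    x = (R_POI + R_lipid + d_NERD)² − (R_POI + R_lipid)²

**Deliberate asymmetry:** the ring exponentials carry *no* `C_P` divisor
while the core term does.  This matches the published form exactly and is
implemented as printed.  `B` reduces to 1 when `f = 1` or `d = 0`, and to
`exp(−2ρπx)` when `f = 0` (an impenetrable shell of outer radius
`R + d`, to first order in coverage).

## Estimator chain

* **MSD.** Pooled time-and-ensemble estimator over all overlapping
  displacement pairs of all tracks (the maximal-pair-usage choice; tracks
  enter with their pair counts, no extra length weighting).  Frame gaps
  contribute only to the lags they span.
* **Diffusion fit.** Least squares of MSD against `t_lag − t_ill/3` over
  the first two lags only; slope/4 = `D`, intercept/4 = `σ²`.  The
  −t_ill/3 term corrects for motion blur (camera averaging over the
  illumination window).  Two points are used because the selection mask
  induces apparent subdiffusion at longer lags (reproduced by the
  simulator; see the acceptance test on mask-induced subdiffusion).
  A negative intercept is truncated to `σ = 0` and flagged.
* **Errors.** Bootstrap over whole trajectories (the natural exchangeable
  unit), SD of the refitted `D`; the ON/OFF ratio error follows by the
  delta method.
* **ON/OFF rule.** A track is ON (OFF) only if *every* localization falls
  on ON (OFF) pixels; mixed tracks are discarded and counted.  The
  published description does not state the edge rule; whole-track discard
  is the conservative choice (no single track mixes two diffusivity
  populations).  A per-localization segmentation mode
  (`rule="segment"`, minimum run length 2) is available for sensitivity
  checks but is not the default.
* **Density.** `ρ_mGFP = (ON − OFF mean)/B_single(t_bulk/t_calib)`; the
  illumination adjustment is linear in exposure time.  The maturation
  correction multiplies by 1 + dark_fraction (×1.2 at the default 20 %
  dark mGFP — i.e. the stated dark share is counted per visible
  chromophore, which is the convention the published ×1.2 factor
  implies), and the oligomer state divides by `n`.  Flat-field correction
  is accepted as a pre-normalized input (a reference-division utility is
  provided; acquiring the reference is out of scope).
* **Radius fit.** Nonlinear least squares with `R` as the sole free
  parameter, unweighted by default (the published analysis does not state
  a weighting; an error-weighted variant is behind a flag).  Initialised
  by a coarse log-grid scan; the reference path uses
  `scipy.optimize.least_squares`, while the high-throughput paths
  (error estimator, grid scan) use a vectorized damped Gauss–Newton
  iteration on batches of datasets; the two agree to <10⁻⁵ nm in tests.
* **Fit error.** Parametric resampling: 1000 synthetic datasets at the
  fitted `R_app`, densities resampled from the empirical per-cell sample
  (a log-normal option exists), per-cell *multiplicative* Gaussian noise
  on ratio (each cell's observed relative error) and on density (a
  profile-level relative SD).  Multiplicative noise is the natural
  reading of "relative experimental error"; an additive variant was not
  published and is not implemented.  The SD of the refitted radii is the
  quoted fit error.  Under the closed-loop test conditions it is
  well calibrated: it matches the empirical seed-to-seed spread of the
  fitted radius (~0.065 nm at n = 88 cells, 5 % errors, R_app = 2.6 nm),
  which also means a ±1 SD interval covers the truth in ~68 % of
  replicates — no more, by construction.

## Nanoenvironment mapping

For each (d, f) combination, a pool of 5000 noisy value pairs is generated
from the ring model under the study's density distribution and error
levels; 1000 study-sized subsets are drawn and fitted with the bare
obstacle model; the mean and SD of `R_app − R_lipid` over iterations are
the modeled expectation.  Classification against the experimental
(mean, err):

* *consistent* — experimental mean inside the modeled ± SD band;
* *borderline* — means outside each other's bands but intervals overlap;
* *not consistent* — disjoint intervals.

Two published descriptions of this rule disagree (one pivots on the d = 0
scenario's interval); the interval rule above is the default and the
alternative is implemented as `classify_nerd_baseline_rule`.  The default
grid is d ∈ {0, 0.35, …, 2.1} nm (0.7 nm ≈ one lipid layer) ×
f ∈ {0.05, …, 0.95} — 7 × 19 = 133 combinations; the published grid count
is 133 but its exact values are not printed, so the grid is fully
configurable.

Because the experimental radius fluctuates between replicate studies with
the same SD as the modeled band, the *consistent* label has ~68 %
replicate stability at the generating truth; consistent-or-borderline is
the stable statement (10/10 in the planted-ring test), and exclusion of
strongly wrong scenarios (≥4 SD away) is highly reproducible.

## Structure-derived radii

Outer-leaflet atoms (centre z in the closed slab [0, z_top], z_top from
the OPM DUM marker planes or supplied explicitly) are projected onto the
membrane plane as discs of their Bondi van der Waals radii; the convex
hull of the *disc set* (not of the centres — the atoms have size) defines
the cross-sectional area, and the equal-area circular radius is reported.
Hull areas agree with a 0.1 Å rasterization oracle to <0.5 %.  Waters are
always excluded; other heteroatoms (e.g. cholesterol) are excluded unless
requested.  Multi-chain files are processed as provided; no symmetry
expansion is performed.

The lipid tracer radius comes from the area per lipid of C18 sphingomyelin
(0.625 nm² → 0.446 nm); the maximal estimate adds the footprint of the
rigid triazole in the labelled headgroup.  The shipped default of
0.29 nm² for that footprint is back-calculated from the published bracket
midpoint 0.49 ± 0.05 nm, since the footprint itself is not printed.

## Synthetic data generator

The generator emulates the study conditions: Poisson-placed immobile disc
obstacles at 10²–10³ µm⁻², Brownian tracers with `D = 1 µm²/s`, 10 ms
frames (3 ms illumination + 7 ms delay), 40 nm localization noise, 3 µm
dots on a 6 µm pitch, and per-cell multiplicative measurement noise
(5 % relative on density and ratio in the closed-loop tests, matching the
order of the per-cell experimental errors; study size n = 88 cells and
densities uniform on 0–2000 µm⁻², the range spanned by the densest
published dataset).

Numerical choices:

* **Obstacle collisions** by move rejection (stay put if the proposed
  sub-step ends inside a core), which has the correct uniform equilibrium
  for small steps; the rms sub-step is capped at `core_radius/5`
  (`SimConfig.for_field`), and a violated cap triggers a warning.
* **Ring slowdown** by scaling the proposed displacement with `√f` when
  the sub-step *starts* inside an annulus (local `D = f·D_free`;
  starting-point rule at the boundary).
* **Motion blur** as the mean of all sub-step positions inside the
  illumination window (≥10 samples at the defaults); localization noise
  is added per frame after blurring.
* **Boundaries** periodic for the dynamics; mask clipping is applied only
  at the analysis stage, mirroring the experiment.  Coordinates are
  stored unwrapped so MSDs need no unwrapping step.
* **Percolation estimator**: overlapping discs clustered with union-find
  (KD-tree neighbour pairs + connected components); a replicate spans if
  one cluster touches the left *and* right box edge.  Single-direction
  crossing is used because its probability at the threshold is ½ in a
  square, making the 50 % bisection point unbiased to leading order;
  the either-direction rule (~0.68 crossing probability at threshold,
  hence a low-biased 50 % point — measured ≈0.669 at box = 100 R) is
  available via `rule="either"`.  Default box = 200 disc radii,
  200 replicates per density, 10 bisection steps; quoted SE combines the
  binomial uncertainty mapped through the fitted local slope of the
  spanning curve with the residual bracket.

What the generator does *not* emulate: photophysics (blinking,
bleaching, variable brightness), spot-detection and linking errors,
membrane topography, obstacle mobility or clustering, non-circular
obstacles, and cell-to-cell biological variability beyond the density
distribution.  Passing closed-loop tests therefore demonstrates that the
estimator chain is self-consistent and correctly calibrated under the
stated noise model — not that the model assumptions hold in cells.

## Problem sizes

The test suite runs closed-loop recoveries at the published study scale
(88 cells, 1000-dataset error estimates, full 133-cell grid scans over
10 seeds), tracer simulations with 2000–6000 tracers, and percolation
estimates with 2000 Monte-Carlo replicates in a 200-radius box; the whole
suite completes in a few minutes on one CPU.  The acceptance script uses
the same percolation settings.

## Limitations

* **The mobility formula is an empirical calibration, not hard-disc
  physics.**  The package's own Brownian-dynamics cross-check (reflecting
  discs, resolved sub-steps, lags 2–5 frames) yields mobility ratios of
  0.93/0.87/0.75/0.59 at coverages 0.05/0.1/0.2/0.3 — close to 2D
  effective-medium expectations — whereas the percolation-form formula
  predicts 0.73/0.62/0.47/0.36.  A hard-disc system cannot produce the
  formula's strong low-coverage slowdown (long-time D is bounded below by
  the effective-medium value ≈ 1 − 2C at small C), so the formula must
  fold in additional physics of the original calibration simulations
  (unpublished ingredients) or of the experiment.  The cross-check test
  records this divergence; radii fitted with the formula inherit its
  calibration and are comparable *within* the assay, but should not be
  read as literal hard-disc radii.
* The fit error is a calibrated 1σ; consumers wanting coverage
  guarantees should scale it accordingly.
* The oriented-structure module trusts the OPM frame; structures without
  DUM markers need an explicit z_top.
* Cholesterol-bridged dimer geometries depend on the deposited assembly;
  no symmetry reconstruction is attempted.
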