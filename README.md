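# nerdmap

Mapping the lipid nanoenvironment of immobilized transmembrane proteins
from single-molecule lipid-tracer diffusion.

## The problem

Transmembrane proteins may carry a shell of tightly associated ("boundary"
or annular) lipids.  A micropatterning assay makes this question
quantitative: an mGFP-tagged protein of interest (POI) is immobilized on
antibody micropatterns (3 µm dots, 6 µm pitch) in the live-cell plasma
membrane, and a fluorescent lipid tracer is tracked by single-molecule
TIRF microscopy.  Immobilized proteins act as steric obstacles, so the
tracer's diffusion coefficient inside the protein-enriched dots (ON) drops
relative to the depleted surround (OFF).  How fast it drops with protein
density encodes the *apparent in-plane radius* of the obstacle — protein
plus any lipid shell that moves with it.

`nerdmap` implements the full analysis chain and a Brownian-dynamics
simulator that generates every input synthetically:

* **tracking** — pooled mean-square displacement of trajectory tables,
  ON/OFF classification by a pattern mask, and the motion-blur-corrected
  two-point fit `MSD(t) = 4D(t − t_ill/3) + 4σ²` with bootstrap errors;
* **density** — molecular counting: bulk pattern brightness divided by
  single-mGFP brightness, with illumination scaling, the ×1.2 dark-mGFP
  maturation correction and oligomer reinterpretation;
* **model** — the percolation-based obstacle model
  `D_ON/D_OFF = 1 − √(1 − exp(−ρπR²/C_P))` with `C_P ≈ 0.676` (the
  critical area coverage of overlapping discs), its extension for a ring
  nanoenvironment of width `d_NERD` and reduced relative diffusivity
  `f_NERD`, the one-parameter fit of the apparent radius `R_app`, and the
  simulated-dataset fit-error estimator;
* **mapping** — the (d_NERD, f_NERD) grid scan that classifies each
  candidate ring as consistent / borderline / not consistent with a
  measured radius;
* **structure** — the in-plane equal-area radius of a membrane protein
  from an OPM-oriented PDB file (outer-leaflet atoms, convex hull of the
  van-der-Waals disc projection) and the lipid tracer radius from the
  area per lipid;
* **simulate** — Poisson disc obstacle fields, tracers with reflecting
  cores and reduced-diffusivity annuli, motion blur, localization noise,
  pattern masks, and a union-find spanning-cluster estimator of the
  percolation threshold.

## Worked example

A synthetic study of 88 cells mimicking a GPCR-sized protein (combined
tracer+protein radius 2.60 nm, densities 0–2000 µm⁻², 5 % measurement
errors), fitted and scanned for admissible ring nanoenvironments:

```python
import nerdmap as nm
from nerdmap.mapping import DatasetProfile, scan_grid

params = nm.NERDParams(r_poi=2.11, r_lipid=0.49)  # combined radius 2.60 nm
dataset = nm.generate_cell_dataset(
    params, lambda rng, n: rng.uniform(0, 2000, n),
    rel_err_density=0.05, rel_err_ratio=0.05, n_cells=88, seed=11)
fit = nm.fit_with_error(dataset, n_sim=1000, seed=11, rel_err_density=0.05)
print(f"R_app      = {fit.r_app:.2f} +- {fit.r_app_error:.2f} nm")
print(f"R_POI,app  = {fit.r_poi_app:.2f} +- {fit.r_poi_app_error:.2f} nm")

profile = DatasetProfile.from_study(dataset, r_poi=1.94,
                                    rel_err_density=0.05)
matrix = scan_grid(profile, (fit.r_poi_app, fit.r_poi_app_error), seed=11)
print(f"grid cells = {matrix.n_combinations}")
print(f"(d=0.7 nm, f=0.5)  -> {matrix.label_of(0.7, 0.5)}")
print(f"(d=0.7 nm, f=0.1)  -> {matrix.label_of(0.7, 0.1)}")
```

prints

```
R_app      = 2.55 +- 0.07 nm
R_POI,app  = 2.06 +- 0.07 nm
grid cells = 133
(d=0.7 nm, f=0.5)  -> consistent
(d=0.7 nm, f=0.1)  -> not_consistent
```

The fit recovers the planted radius within its simulated fit error
(truth: R_app = 2.60 nm, R_POI,app = 2.11 nm).  The 7 × 19 grid scan then
shows what such a dataset can and cannot rule out: a single lipid layer
(d = 0.7 nm) with mildly reduced mobility is indistinguishable from a bare
protein, while the same layer with a 90 % mobility reduction would have
inflated the apparent radius measurably and is excluded.

The same stages are available from the shell:
`nerdmap simulate | percolation | analyze | fit | scan | structure-radius`
(see `nerdmap --help`).

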