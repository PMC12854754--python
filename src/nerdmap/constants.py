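"""Physical constants and assay defaults shared across the package.

All lengths follow the package-wide unit convention: radii and widths in
nanometres, coordinates and box sizes in micrometres, surface densities in
µm⁻², times in seconds.
"""

#: Critical area coverage of randomly placed overlapping discs at the 2D
#: continuum percolation threshold.  Dimensionless; independent of disc size.
PERCOLATION_COVERAGE = 0.676

#: Area per lipid of stearoyl (C18) sphingomyelin, nm², from scattering data.
AREA_PER_LIPID = 0.625

#: In-plane footprint of the rigid triazole moiety carried in the headgroup
#: of the labelled sphingomyelin tracer, nm².  Added to the area per lipid
#: for the maximal tracer-size estimate (bracket 0.446-0.54 nm, midpoint
#: 0.49 ± 0.05 nm).
TRIAZOLE_AREA = 0.29

#: Default lipid tracer radius, nm (midpoint of the min/max bracket).
R_LIPID = 0.49

#: Fraction of mGFP tags with an immature (dark) chromophore.
DARK_FRACTION = 0.20

#: Camera illumination time per frame during tracer tracking, s.
T_ILL = 0.003

#: Frame-to-frame spacing during tracer tracking (illumination + delay), s.
FRAME_SPACING = 0.010

#: Typical single-molecule localization precision, µm (40 nm).
SIGMA_LOC = 0.040

#: nm² → µm² conversion applied wherever a density in µm⁻² multiplies a
#: squared radius in nm.  Lives here, and only here, so the mobility model
#: formulas read exactly as published.
NM2_PER_UM2 = 1e-6
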