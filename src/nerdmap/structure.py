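"""In-plane protein radius from membrane-oriented structures.

The steric size a lipid tracer encounters is estimated from an oriented
structure (membrane normal along z, bilayer midplane at z = 0, as provided
by the OPM database): the atoms of the outer membrane leaflet are projected
onto the membrane plane as discs of their van der Waals radii, the convex
hull of the disc set is taken, and the radius of a circular obstacle of
identical cross-sectional area is reported.  A companion helper derives the
lipid tracer radius from the area per lipid.

Coordinates are in Å throughout; reported radii in nm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .constants import AREA_PER_LIPID, TRIAZOLE_AREA

logger = logging.getLogger(__name__)

__all__ = [
    "VDW_RADII",
    "AtomSet",
    "LipidRadius",
    "load_oriented_structure",
    "select_leaflet",
    "inplane_hull_radius",
    "lipid_tracer_radius",
]

#: Van der Waals radii, Å, keyed by element symbol (Bondi 1964 values with
#: the common extensions for main-group elements).
VDW_RADII = {
    "H": 1.20, "HE": 1.40,
    "LI": 1.82, "BE": 1.53, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "NE": 1.54,
    "NA": 2.27, "MG": 1.73, "AL": 1.84, "SI": 2.10, "P": 1.80, "S": 1.80,
    "CL": 1.75, "AR": 1.88,
    "K": 2.75, "CA": 2.31, "ZN": 1.39, "FE": 1.94, "MN": 1.97, "CU": 1.40,
    "NI": 1.63, "CO": 1.92, "SE": 1.90, "BR": 1.85, "KR": 2.02,
    "I": 1.98, "XE": 2.16, "CD": 1.58, "HG": 1.55,
}


@dataclass(frozen=True)
class AtomSet:
    """Van-der-Waals-tagged atoms in the oriented membrane frame.

    ``coords`` are (n, 3) in Å with z = 0 at the bilayer midplane;
    ``z_top`` is the outer-leaflet boundary (half the hydrophobic
    thickness) when known.
    """

    elements: tuple
    coords: np.ndarray
    vdw: np.ndarray
    z_top: float | None = None
    source: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        vdw = np.asarray(self.vdw, dtype=float).reshape(-1)
        if len(coords) != len(vdw) or len(coords) != len(self.elements):
            raise ValueError("elements, coords and vdw lengths differ")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite atom coordinates")
        if np.any(vdw <= 0):
            raise ValueError("van der Waals radii must be > 0")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "vdw", vdw)
        object.__setattr__(self, "elements", tuple(self.elements))

    def __len__(self) -> int:
        return len(self.vdw)


def load_oriented_structure(path, z_top: float | None = None,
                            include_hetero: bool = False,
                            fallback_radius: float = 1.70) -> AtomSet:
    """Read an OPM-oriented PDB file into an :class:`AtomSet`.

    Waters are always excluded; other heteroatoms (ligands, lipids,
    cholesterol) are excluded by default and retained with
    ``include_hetero=True``.  OPM DUM marker atoms are never part of the
    atom set, but when present their maximal z defines the outer-leaflet
    boundary ``z_top``; otherwise ``z_top`` must be supplied for leaflet
    selection to work.  Unknown elements get ``fallback_radius`` with a
    warning.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    vdw: list[float] = []
    dum_z: list[float] = []
    n_waters = 0
    unknown: set[str] = set()
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.name == "DUM":
                dum_z.extend(a.pos.z for a in residue)
                continue
            if residue.is_water():
                n_waters += len(residue)
                continue
            if residue.het_flag == "H" and not include_hetero:
                continue
            for atom in residue:
                el = atom.element.name.upper()
                r = VDW_RADII.get(el)
                if r is None:
                    unknown.add(el)
                    r = fallback_radius
                elements.append(el)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                vdw.append(r)
    if n_waters:
        logger.info("%s: excluded %d water atoms", path, n_waters)
    if unknown:
        warnings.warn(f"unknown element(s) {sorted(unknown)}; using fallback "
                      f"vdW radius {fallback_radius} Å", stacklevel=2)
    if dum_z and z_top is None:
        z_top = float(np.max(dum_z))
    if z_top is None:
        raise ValueError(
            f"{path}: no membrane-orientation metadata (DUM atoms) found "
            "and no z_top supplied")
    if not elements:
        raise ValueError(f"{path}: no atoms read")
    return AtomSet(elements=tuple(elements), coords=np.array(coords),
                   vdw=np.array(vdw), z_top=z_top, source=str(path))


def select_leaflet(atoms: AtomSet, z_min: float = 0.0,
                   z_max: float | None = None) -> AtomSet:
    """Atoms whose centre lies in the slab z ∈ [z_min, z_max] (closed).

    The default slab [0, z_top] is the outer (extracellular) membrane
    leaflet in the OPM frame.
    """
    if z_max is None:
        if atoms.z_top is None:
            raise ValueError("z_max not given and atom set has no z_top")
        z_max = atoms.z_top
    if z_min >= z_max:
        raise ValueError("z_min must be < z_max")
    z = atoms.coords[:, 2]
    keep = (z >= z_min) & (z <= z_max)
    if not keep.any():
        raise ValueError(f"no atoms in leaflet slab [{z_min}, {z_max}] Å")
    return replace(atoms,
                   elements=tuple(np.asarray(atoms.elements)[keep]),
                   coords=atoms.coords[keep], vdw=atoms.vdw[keep])


def _hull_polygon(atoms: AtomSet, buffered: bool = True, quad_segs: int = 96):
    """Convex hull (shapely polygon) of the z-projected vdW disc set, Å."""
    import shapely
    from shapely.geometry import MultiPoint, Point

    xy = atoms.coords[:, :2]
    if not buffered:
        return MultiPoint(xy).convex_hull
    if len(atoms) > 64:
        # only discs that can touch the hull of the disc set matter:
        # keep atoms within 2·max(vdw) of the point-hull boundary
        hull = MultiPoint(xy).convex_hull
        margin = 2.0 * float(atoms.vdw.max())
        inner = hull.buffer(-margin)
        keep = [i for i in range(len(atoms))
                if not inner.contains(Point(xy[i]))]
    else:
        keep = range(len(atoms))
    discs = [Point(xy[i]).buffer(atoms.vdw[i], quad_segs=quad_segs)
             for i in keep]
    return shapely.GeometryCollection(discs).convex_hull


def inplane_hull_radius(atoms: AtomSet, buffered: bool = True) -> float:
    """Equal-area in-plane radius of the projected atom set, nm.

    Each atom is projected onto the membrane plane as a disc of its van der
    Waals radius; the area of the convex hull of the disc set defines a
    circular obstacle of identical area whose radius is returned.
    ``buffered=False`` uses the hull of the atom centres instead (for
    sensitivity checks).
    """
    if len(atoms) == 0:
        raise ValueError("empty atom set")
    area_A2 = _hull_polygon(atoms, buffered=buffered).area
    return float(np.sqrt(area_A2 / np.pi) / 10.0)


@dataclass(frozen=True)
class LipidRadius:
    """Lipid tracer radius bracket, nm."""

    r_min: float
    r_max: float

    @property
    def r_mid(self) -> float:
        return 0.5 * (self.r_min + self.r_max)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.r_max - self.r_min)


def lipid_tracer_radius(area_per_lipid: float = AREA_PER_LIPID,
                        headgroup_extra_area: float = TRIAZOLE_AREA
                        ) -> LipidRadius:
    """Lipid tracer radius from the area per lipid, nm.

    The minimal estimate is the equal-area radius of the bare lipid; the
    maximal estimate additionally counts the footprint of the rigid
    headgroup label moiety (the triazole of the clicked fluorophore
    linker).  Defaults give the sphingomyelin tracer bracket
    0.45–0.54 nm, midpoint 0.49 ± 0.05 nm.
    """
    if area_per_lipid <= 0 or headgroup_extra_area < 0:
        raise ValueError("areas must be positive")
    r_min = float(np.sqrt(area_per_lipid / np.pi))
    r_max = float(np.sqrt((area_per_lipid + headgroup_extra_area) / np.pi))
    return LipidRadius(r_min=r_min, r_max=r_max)
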