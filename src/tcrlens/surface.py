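"""Solvent-accessible surface area, interface burial and shape complementarity.

SASA uses Shrake-Rupley quadrature: each atom is covered with a
deterministic golden-spiral point set on a sphere of radius
(r_vdw + probe); the accessible fraction is the share of points not
inside any neighbour sphere, scaled by the full sphere area.  BSASA is
SASA(TCR alone) + SASA(pHLA alone) - SASA(complex), with the components
extracted by chain role without moving any atoms.

Shape complementarity follows Lawrence & Colman: each side's dot surface
is trimmed to an interface band near the other side; every point is
scored against its nearest partner point as (n_a . -n_b) exp(-w d^2),
and the statistic is the mean of the two per-side medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import ComplexAnnotation, MolecularStructure

__all__ = [
    "BONDI_RADII",
    "SurfaceResult",
    "ShapeComplementarityResult",
    "sphere_points",
    "atom_radii",
    "compute_sasa",
    "compute_bsasa",
    "compute_shape_complementarity",
]

#: Bondi-style van der Waals radii (Angstrom) by element symbol.
BONDI_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "SE": 1.90, "FE": 1.40, "ZN": 1.39, "MG": 1.73,
    "NA": 2.27, "K": 2.75, "CA": 2.31, "MN": 1.40,
}


class RadiusError(KeyError):
    """Raised when an element has no tabulated radius."""


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def atom_radii(s: MolecularStructure, radii: dict | None = None) -> np.ndarray:
    table = radii or BONDI_RADII
    out = np.empty(s.n_atoms, dtype=float)
    for i, el in enumerate(s.element):
        r = table.get(str(el).upper())
        if r is None:
            raise RadiusError(
                f"no radius for element {el!r} (atom {s.chain_id[i]}/"
                f"{s.resnum[i]}/{s.name[i]})"
            )
        out[i] = r
    return out


@dataclass
class SurfaceResult:
    per_atom: np.ndarray          # A^2, aligned with the atom indices used
    atom_indices: np.ndarray      # indices into the parent structure
    total: float
    probe_radius: float
    quadrature_points: int

    def total_by_chain(self, s: MolecularStructure) -> dict[str, float]:
        out: dict[str, float] = {}
        for idx, area in zip(self.atom_indices, self.per_atom):
            ch = str(s.chain_id[idx])
            out[ch] = out.get(ch, 0.0) + float(area)
        return out


def compute_sasa(
    s: MolecularStructure,
    probe: float = 1.4,
    n_points: int = 960,
    mask: np.ndarray | None = None,
    coords: np.ndarray | None = None,
    radii: dict | None = None,
) -> SurfaceResult:
    """Shrake-Rupley SASA of the atoms selected by ``mask``.

    The default selection is heavy, non-water, non-hetero atoms.  Only the
    selected atoms exist for the calculation, so passing a chain mask
    computes that component "alone" without moving it.
    """
    if mask is None:
        mask = s.heavy_mask()
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return SurfaceResult(np.zeros(0), idx, 0.0, probe, n_points)
    xyz = (s.coords if coords is None else np.asarray(coords, float))[idx]
    rad = atom_radii(s, radii)[idx] + probe

    pts = sphere_points(n_points)
    tree = cKDTree(xyz)
    r_max = rad.max()
    per_atom = np.zeros(len(idx))
    for i in range(len(idx)):
        neighbors = tree.query_ball_point(xyz[i], rad[i] + r_max)
        neighbors = [j for j in neighbors if j != i]
        surface = xyz[i] + rad[i] * pts
        if neighbors:
            nb = np.array(neighbors, dtype=int)
            d2 = ((surface[:, None, :] - xyz[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (rad[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * rad[i] ** 2
    return SurfaceResult(
        per_atom=per_atom, atom_indices=idx, total=float(per_atom.sum()),
        probe_radius=probe, quadrature_points=n_points,
    )


def compute_bsasa(
    s: MolecularStructure,
    a: ComplexAnnotation,
    probe: float = 1.4,
    n_points: int = 960,
    coords: np.ndarray | None = None,
    half: bool = False,
) -> float:
    """Buried SASA of the TCR / pHLA interface (A^2).

    Total burial by default; ``half=True`` reports the per-side convention
    (total / 2).
    """
    base = s.heavy_mask()
    tcr = base & s.chain_mask(a.tcr_chains())
    phla = base & s.chain_mask(a.phla_chains())
    both = tcr | phla
    kw = dict(probe=probe, n_points=n_points, coords=coords)
    b = (
        compute_sasa(s, mask=tcr, **kw).total
        + compute_sasa(s, mask=phla, **kw).total
        - compute_sasa(s, mask=both, **kw).total
    )
    return b / 2.0 if half else b


# ---------------------------------------------------------------------------
# Shape complementarity
# ---------------------------------------------------------------------------

@dataclass
class ShapeComplementarityResult:
    sc: float
    w_parameter: float
    band: float
    interface_point_count: tuple[int, int]
    median_a_to_b: float
    median_b_to_a: float


def _dot_surface(
    xyz: np.ndarray, rad: np.ndarray, n_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exposed dot surface (points, outward normals) of one atom set."""
    pts = sphere_points(n_points)
    tree = cKDTree(xyz)
    r_max = rad.max()
    all_pts, all_nrm = [], []
    for i in range(len(xyz)):
        neighbors = [j for j in tree.query_ball_point(xyz[i], rad[i] + r_max)
                     if j != i]
        surface = xyz[i] + rad[i] * pts
        if neighbors:
            nb = np.array(neighbors, dtype=int)
            d2 = ((surface[:, None, :] - xyz[nb][None, :, :]) ** 2).sum(axis=2)
            keep = ~(d2 < (rad[nb] ** 2)[None, :]).any(axis=1)
        else:
            keep = np.ones(len(surface), dtype=bool)
        if keep.any():
            all_pts.append(surface[keep])
            all_nrm.append(pts[keep])
    if not all_pts:
        return np.zeros((0, 3)), np.zeros((0, 3))
    return np.vstack(all_pts), np.vstack(all_nrm)


def compute_shape_complementarity(
    s: MolecularStructure,
    a: ComplexAnnotation,
    w: float = 0.5,
    band: float = 1.5,
    n_points: int = 240,
    probe: float = 0.0,
    radii: dict | None = None,
) -> ShapeComplementarityResult:
    """Lawrence-Colman shape complementarity of the TCR / pHLA interface.

    ``w`` (A^-2) is the distance-weighting parameter; ``band`` (A) selects
    interface points by distance to the other surface.  ``probe`` > 0
    inflates both surfaces (solvent-accessible variant); the default 0
    scores the van der Waals dot surfaces.
    """
    base = s.heavy_mask()
    masks = (base & s.chain_mask(a.tcr_chains()),
             base & s.chain_mask(a.phla_chains()))
    rad_all = atom_radii(s, radii) + probe
    surfaces = []
    for m in masks:
        idx = np.flatnonzero(m)
        if len(idx) == 0:
            raise ValueError("empty atom selection for one interface side")
        surfaces.append(_dot_surface(s.coords[idx], rad_all[idx], n_points))

    (pa, na), (pb, nb) = surfaces
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("empty dot surface")
    tree_a, tree_b = cKDTree(pa), cKDTree(pb)

    def side_scores(pts, nrms, other_tree, other_nrm):
        d, j = other_tree.query(pts, k=1)
        in_band = d <= band
        if not in_band.any():
            raise ValueError("no interface points within the band; "
                             "surfaces may not be in contact")
        d, j = d[in_band], j[in_band]
        dots = np.einsum("ij,ij->i", nrms[in_band], -other_nrm[j])
        return dots * np.exp(-w * d * d)

    sa = side_scores(pa, na, tree_b, nb)
    sb = side_scores(pb, nb, tree_a, na)
    med_ab, med_ba = float(np.median(sa)), float(np.median(sb))
    return ShapeComplementarityResult(
        sc=0.5 * (med_ab + med_ba), w_parameter=w, band=band,
        interface_point_count=(len(sa), len(sb)),
        median_a_to_b=med_ab, median_b_to_a=med_ba,
    )
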