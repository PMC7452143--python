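"""Binding-geometry metrics for TCR-pHLA complexes.

The reference frame for all docking metrics is the peptide-binding groove:
its origin is the centroid of the peptide C-alpha atoms, its x axis the
peptide principal axis (oriented N to C), its y axis points from the
alpha2-helix side toward the alpha1-helix side, and z = x cross y points
out of the groove toward the TCR.  The crossing angle is the unsigned
in-plane angle between the V-alpha to V-beta interdomain vector and the
peptide axis; the docking footprint is the in-plane displacement of the
combined variable-domain centroid from the groove origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import AlignmentError, ComplexAnnotation, MolecularStructure, _align

__all__ = [
    "GrooveFrame",
    "CrossingAngleResult",
    "FootprintPosition",
    "GeometryError",
    "compute_groove_frame",
    "compute_crossing_angle",
    "compute_footprint",
    "loop_rmsd",
    "superpose",
    "kabsch",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class GeometryError(ValueError):
    """Raised for degenerate geometry (collinear axes, too few atoms)."""


@dataclass
class GrooveFrame:
    """Right-handed orthonormal frame anchored on the peptide groove."""

    origin: np.ndarray
    x_axis: np.ndarray   # peptide principal axis, N -> C
    y_axis: np.ndarray   # alpha2 side -> alpha1 side, in the groove plane
    z_axis: np.ndarray   # groove -> TCR

    def project(self, point: np.ndarray) -> tuple[float, float]:
        d = np.asarray(point, dtype=float) - self.origin
        return float(d @ self.x_axis), float(d @ self.y_axis)


@dataclass
class CrossingAngleResult:
    angle: float                 # degrees, [0, 180)
    v_alpha_centroid: np.ndarray
    v_beta_centroid: np.ndarray
    definition_tag: str


@dataclass
class FootprintPosition:
    x: float   # Angstrom along the peptide axis (N terminus negative)
    y: float   # Angstrom across the helices (alpha1 side positive)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-8:
        raise GeometryError(f"degenerate geometry: zero-length {what}")
    return v / n


def compute_groove_frame(
    s: MolecularStructure, a: ComplexAnnotation
) -> GrooveFrame:
    """Construct the groove frame from peptide and HLA helix C-alpha atoms."""
    pep_chain = a.chain_of("peptide")
    pep_idx = s.ca_indices(pep_chain)
    if len(pep_idx) < 8:
        raise GeometryError(f"peptide has {len(pep_idx)} CA atoms, need >= 8")
    pep = s.coords[pep_idx]
    origin = pep.mean(axis=0)
    centered = pep - origin
    # principal axis of the peptide trace
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    x_axis = vt[0]
    if (pep[-1] - pep[0]) @ x_axis < 0:
        x_axis = -x_axis

    if not a.groove_helix_ranges:
        raise GeometryError("annotation lacks groove_helix_ranges (alpha1/alpha2)")
    hla_chain = a.chain_of("HLA_heavy")
    cents = {}
    for key in ("alpha1", "alpha2"):
        rng = a.groove_helix_ranges.get(key)
        if rng is None:
            raise GeometryError(f"groove helix range {key!r} missing")
        idx = s.ca_indices(hla_chain, rng)
        if len(idx) == 0:
            raise GeometryError(f"no CA atoms in {key} range {rng}")
        cents[key] = s.coords[idx].mean(axis=0)
    y_raw = cents["alpha1"] - cents["alpha2"]
    y_perp = y_raw - (y_raw @ x_axis) * x_axis
    y_axis = _unit(y_perp, "helix-separation axis (helix centroids collinear "
                           "with the peptide axis)")
    z_axis = np.cross(x_axis, y_axis)
    return GrooveFrame(origin=origin, x_axis=x_axis, y_axis=y_axis, z_axis=z_axis)


def _domain_centroid(
    s: MolecularStructure, a: ComplexAnnotation, role: str, rule: str
) -> np.ndarray:
    chain = a.chain_of(role)
    rng = a.variable_domain_ranges.get(role)
    if rng is None:
        raise GeometryError(f"annotation lacks variable-domain range for {role}")
    if rule == "domain_ca":
        idx = s.ca_indices(chain, rng)
        if len(idx) == 0:
            raise GeometryError(f"no CA atoms in variable domain of {role}")
        return s.coords[idx].mean(axis=0)
    if rule == "disulfide_ca":
        pos = a.cys_positions.get(role)
        if pos is None:
            raise GeometryError(
                f"no conserved cysteine positions annotated for {role}; "
                "use centroid_rule='domain_ca'"
            )
        pts = []
        for p in pos:
            m = (s.chain_id == chain) & (s.resnum == p) & (s.name == "CA")
            hit = np.flatnonzero(m)
            if len(hit) == 0:
                raise GeometryError(
                    f"cysteine CA at {chain}/{p} not found; "
                    "use centroid_rule='domain_ca'"
                )
            pts.append(s.coords[hit[0]])
        return np.mean(pts, axis=0)
    raise ValueError(f"unknown centroid rule {rule!r}")


def compute_crossing_angle(
    s: MolecularStructure,
    a: ComplexAnnotation,
    centroid_rule: str = "disulfide_ca",
) -> CrossingAngleResult:
    """Unsigned in-plane angle between the Valpha->Vbeta vector and the
    peptide axis, in degrees within [0, 180)."""
    frame = compute_groove_frame(s, a)
    ca = _domain_centroid(s, a, "TCR_alpha", centroid_rule)
    cb = _domain_centroid(s, a, "TCR_beta", centroid_rule)
    v = cb - ca
    v_plane = v - (v @ frame.z_axis) * frame.z_axis
    v_plane = _unit(v_plane, "interdomain vector (perpendicular to groove plane)")
    cosang = np.clip(v_plane @ frame.x_axis, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang))) % 180.0
    return CrossingAngleResult(
        angle=angle, v_alpha_centroid=ca, v_beta_centroid=cb,
        definition_tag=centroid_rule,
    )


def compute_footprint(
    s: MolecularStructure, a: ComplexAnnotation
) -> FootprintPosition:
    """In-plane displacement of the combined Valpha+Vbeta CA centroid."""
    frame = compute_groove_frame(s, a)
    pts = []
    for role in ("TCR_alpha", "TCR_beta"):
        chain = a.chain_of(role)
        rng = a.variable_domain_ranges.get(role)
        if rng is None:
            raise GeometryError(f"annotation lacks variable-domain range for {role}")
        idx = s.ca_indices(chain, rng)
        if len(idx) == 0:
            raise GeometryError(f"no CA atoms in variable domain of {role}")
        pts.append(s.coords[idx])
    centroid = np.vstack(pts).mean(axis=0)
    x, y = frame.project(centroid)
    return FootprintPosition(x=x, y=y)


# ---------------------------------------------------------------------------
# Superposition and loop displacement
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto ref.

    Returns (R, t) such that ``mobile @ R.T + t`` best fits ``ref``.
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - mc @ R.T
    return R, t


def superpose(
    mobile: MolecularStructure,
    ref: MolecularStructure,
    mobile_idx: np.ndarray,
    ref_idx: np.ndarray,
) -> MolecularStructure:
    """Rigidly superpose ``mobile`` onto ``ref`` using matched atom indices."""
    if len(mobile_idx) != len(ref_idx) or len(mobile_idx) < 3:
        raise GeometryError("need >= 3 matched atoms for superposition")
    R, t = kabsch(mobile.coords[mobile_idx], ref.coords[ref_idx])
    return mobile.with_coords(mobile.coords @ R.T + t)


def _matched_ca(
    a: MolecularStructure, b: MolecularStructure, chain_a: str, chain_b: str
) -> tuple[np.ndarray, np.ndarray]:
    ids_a = {(int(a.resnum[i]), str(a.icode[i])): i for i in a.ca_indices(chain_a)}
    ids_b = {(int(b.resnum[i]), str(b.icode[i])): i for i in b.ca_indices(chain_b)}
    common = [k for k in ids_a if k in ids_b]
    return (np.array([ids_a[k] for k in common], dtype=int),
            np.array([ids_b[k] for k in common], dtype=int))


def loop_rmsd(
    wt: MolecularStructure,
    wt_annotation: ComplexAnnotation,
    variant: MolecularStructure,
    variant_annotation: ComplexAnnotation,
) -> pd.DataFrame:
    """Per-loop backbone RMSD after superposing on HLA heavy-chain CA atoms.

    Loops are compared position-wise after sequence alignment; backbone
    atoms (N, CA, C, O) missing on either side are skipped and counted.
    A loop without any matched position is flagged not comparable (NaN)
    rather than raising.
    """
    wt_hla = wt_annotation.chain_of("HLA_heavy")
    var_hla = variant_annotation.chain_of("HLA_heavy")
    idx_var, idx_wt = _matched_ca(variant, wt, var_hla, wt_hla)
    if len(idx_wt) < 3:
        raise GeometryError("fewer than 3 matched HLA CA atoms for superposition")
    var_fit = superpose(variant, wt, idx_var, idx_wt)

    rows = []
    labels = sorted(set(wt_annotation.loop_ranges) & set(variant_annotation.loop_ranges))
    for lbl in labels:
        role = "TCR_alpha" if lbl.endswith("a") else "TCR_beta"
        ch_wt = wt_annotation.chain_of(role)
        ch_var = variant_annotation.chain_of(role)
        lo_w, hi_w = wt_annotation.loop_ranges[lbl]
        lo_v, hi_v = variant_annotation.loop_ranges[lbl]

        def loop_residues(s, ch, lo, hi):
            seq, ids = s.chain_sequence(ch)
            keep = [(c, rid) for c, rid in zip(seq, ids) if lo <= rid[0] <= hi]
            return "".join(c for c, _ in keep), [rid for _, rid in keep]

        seq_w, ids_w = loop_residues(wt, ch_wt, lo_w, hi_w)
        seq_v, ids_v = loop_residues(var_fit, ch_var, lo_v, hi_v)
        if not seq_w or not seq_v:
            rows.append({"loop": lbl, "rmsd": np.nan, "n_atoms": 0,
                         "n_missing": 0, "comparable": False})
            continue
        if len(seq_w) == len(seq_v):
            pairs = list(zip(ids_w, ids_v))
        else:
            try:
                aln = _align(seq_w, seq_v)
            except Exception:
                pairs = []
            else:
                pairs = []
                for (s1, e1), (s2, e2) in zip(*aln.aligned):
                    pairs.extend(
                        (ids_w[s1 + k], ids_v[s2 + k]) for k in range(e1 - s1)
                    )
        deltas = []
        missing = 0
        for (rn_w, ic_w), (rn_v, ic_v) in pairs:
            for atom in BACKBONE_ATOMS:
                try:
                    iw = wt.atom_index(ch_wt, rn_w, atom, ic_w)
                    iv = var_fit.atom_index(ch_var, rn_v, atom, ic_v)
                except KeyError:
                    missing += 1
                    continue
                deltas.append(wt.coords[iw] - var_fit.coords[iv])
        if not deltas:
            rows.append({"loop": lbl, "rmsd": np.nan, "n_atoms": 0,
                         "n_missing": missing, "comparable": False})
        else:
            d = np.array(deltas)
            rows.append({
                "loop": lbl,
                "rmsd": float(np.sqrt(np.mean(np.sum(d * d, axis=1)))),
                "n_atoms": len(deltas),
                "n_missing": missing,
                "comparable": True,
            })
    return pd.DataFrame(rows, columns=["loop", "rmsd", "n_atoms", "n_missing",
                                       "comparable"])
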