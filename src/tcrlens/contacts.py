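"""Atomic contact enumeration and classification across the TCR-pHLA interface.

A contact is any heavy-atom pair with one atom on the TCR (alpha or beta
chain) and one on the peptide or HLA heavy chain within the van der Waals
cutoff (default 4.0 A).  A pair is additionally typed as a hydrogen bond
when a donor heavy atom faces an acceptor within the HB cutoff (3.4 A),
and as a salt bridge when a charged side-chain nitrogen (Lys NZ, Arg
NE/NH1/NH2, optionally protonated His ND1/NE2) faces a carboxylate oxygen
(Asp OD1/OD2, Glu OE1/OE2) within the SB cutoff (3.4 A).  Types are tags
on one row, not exclusive bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import AA3TO1, ComplexAnnotation, MolecularStructure

__all__ = [
    "ContactCriteria",
    "ContactComparison",
    "find_contacts",
    "per_residue_contact_map",
    "compare_contact_tables",
]

CONTACT_COLUMNS = [
    "tcr_chain_role", "tcr_chain", "tcr_resnum", "tcr_resname", "tcr_atom",
    "target", "target_chain", "target_resnum", "target_resname", "target_atom",
    "distance", "is_vdw", "is_hb", "is_sb",
]


@dataclass
class ContactCriteria:
    """Distance cutoffs (Angstrom) and typing switches."""

    vdw_cutoff: float = 4.0
    hb_cutoff: float = 3.4
    sb_cutoff: float = 3.4
    include_hydrogens: bool = False
    his_protonated: bool = False

    def __post_init__(self) -> None:
        if min(self.vdw_cutoff, self.hb_cutoff, self.sb_cutoff) <= 0:
            raise ValueError("all cutoffs must be positive")
        if self.hb_cutoff > self.vdw_cutoff:
            raise ValueError("hb_cutoff must not exceed vdw_cutoff")

    @property
    def search_radius(self) -> float:
        return max(self.vdw_cutoff, self.hb_cutoff, self.sb_cutoff)


# Donor/acceptor typing by (residue, atom).  Backbone N donates (except
# proline), backbone O and OXT accept; side-chain chemistry per residue.
_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "HIS": {"ND1", "NE2"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "MET": {"SD"},
}
_SB_POSITIVE = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}}
_SB_POSITIVE_HIS = {"HIS": {"ND1", "NE2"}}
_SB_NEGATIVE = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}


def _is_donor(resname: str, atom: str) -> bool:
    if atom == "N" and resname != "PRO":
        return True
    return atom in _SIDECHAIN_DONORS.get(resname, ())


def _is_acceptor(resname: str, atom: str) -> bool:
    if atom in ("O", "OXT"):
        return True
    return atom in _SIDECHAIN_ACCEPTORS.get(resname, ())


def _is_sb_pos(resname: str, atom: str, his_protonated: bool) -> bool:
    if atom in _SB_POSITIVE.get(resname, ()):
        return True
    return his_protonated and atom in _SB_POSITIVE_HIS.get(resname, ())


def _is_sb_neg(resname: str, atom: str) -> bool:
    return atom in _SB_NEGATIVE.get(resname, ())


def find_contacts(
    s: MolecularStructure,
    a: ComplexAnnotation,
    criteria: ContactCriteria | None = None,
    coords: np.ndarray | None = None,
) -> pd.DataFrame:
    """Enumerate typed TCR <-> peptide/HLA contacts as a tidy table.

    ``coords`` may override the structure's coordinates (same atom order),
    which is how per-frame contact maps are computed for ensembles.
    Residues without a chemistry entry raise a warning once and contribute
    vdW-only rows.
    """
    criteria = criteria or ContactCriteria()
    xyz = s.coords if coords is None else np.asarray(coords, dtype=float)

    atom_mask = ~s.is_water
    if not criteria.include_hydrogens:
        atom_mask &= ~s.is_hydrogen

    role_of = dict(a.role_map)
    tcr_chains = a.tcr_chains()
    target_chains = [ch for ch, r in a.role_map.items() if r in ("peptide", "HLA_heavy")]
    tcr_idx = np.flatnonzero(atom_mask & s.chain_mask(tcr_chains))
    tgt_idx = np.flatnonzero(atom_mask & s.chain_mask(target_chains))
    if len(tcr_idx) == 0 or len(tgt_idx) == 0:
        return pd.DataFrame(columns=CONTACT_COLUMNS)

    unknown: set[str] = set()
    tree = cKDTree(xyz[tgt_idx])
    hits = tree.query_ball_point(xyz[tcr_idx], r=criteria.search_radius)

    rows = []
    for ti, neighbor_list in zip(tcr_idx, hits):
        if not neighbor_list:
            continue
        t_res, t_atom = str(s.resname[ti]), str(s.name[ti])
        if t_res not in AA3TO1:
            unknown.add(t_res)
        for pj in neighbor_list:
            gj = tgt_idx[pj]
            d = float(np.linalg.norm(xyz[ti] - xyz[gj]))
            g_res, g_atom = str(s.resname[gj]), str(s.name[gj])
            if g_res not in AA3TO1:
                unknown.add(g_res)
            known = t_res in AA3TO1 and g_res in AA3TO1
            is_vdw = d <= criteria.vdw_cutoff
            is_hb = known and d <= criteria.hb_cutoff and (
                (_is_donor(t_res, t_atom) and _is_acceptor(g_res, g_atom))
                or (_is_donor(g_res, g_atom) and _is_acceptor(t_res, t_atom))
            )
            is_sb = known and d <= criteria.sb_cutoff and (
                (_is_sb_pos(t_res, t_atom, criteria.his_protonated)
                 and _is_sb_neg(g_res, g_atom))
                or (_is_sb_pos(g_res, g_atom, criteria.his_protonated)
                    and _is_sb_neg(t_res, t_atom))
            )
            if not (is_vdw or is_hb or is_sb):
                continue
            target_kind = "peptide" if role_of[str(s.chain_id[gj])] == "peptide" else "HLA"
            rows.append((
                role_of[str(s.chain_id[ti])], str(s.chain_id[ti]),
                int(s.resnum[ti]), t_res, t_atom,
                target_kind, str(s.chain_id[gj]),
                int(s.resnum[gj]), g_res, g_atom,
                d, is_vdw, is_hb, is_sb,
            ))
    if unknown:
        warnings.warn(
            f"no chemistry entry for residues {sorted(unknown)}; "
            "treated as vdW-only", stacklevel=2,
        )
    table = pd.DataFrame(rows, columns=CONTACT_COLUMNS)
    return table.sort_values(
        ["tcr_chain", "tcr_resnum", "tcr_atom", "target_chain", "target_resnum",
         "target_atom"],
        kind="stable",
    ).reset_index(drop=True)


def per_residue_contact_map(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a contact table to per-pHLA-residue vdW and HB counts."""
    if table.empty:
        return pd.DataFrame(columns=["target", "target_chain", "target_resnum",
                                     "n_vdw", "n_hb"])
    g = table.groupby(["target", "target_chain", "target_resnum"], sort=True)
    out = g.agg(n_vdw=("is_vdw", "sum"), n_hb=("is_hb", "sum")).reset_index()
    out["n_vdw"] = out["n_vdw"].astype(int)
    out["n_hb"] = out["n_hb"].astype(int)
    return out


@dataclass
class ContactComparison:
    """Contact-count differences (variant minus wild type) and top-contact
    preservation."""

    delta_counts: pd.DataFrame      # index: type; columns: peptide, HLA, total
    preserved_top_contacts: int
    k: int
    top_wt_residues: list[tuple[str, str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "delta_counts": {
                t: {c: int(self.delta_counts.loc[t, c])
                    for c in self.delta_counts.columns}
                for t in self.delta_counts.index
            },
            "preserved_top_contacts": self.preserved_top_contacts,
            "k": self.k,
            "top_wt_residues": [list(r) for r in self.top_wt_residues],
        }


def _counts_by_type_target(table: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(
        0, index=["vdW", "HB", "SB"], columns=["peptide", "HLA", "total"]
    )
    if table.empty:
        return out
    for typ, col in (("vdW", "is_vdw"), ("HB", "is_hb"), ("SB", "is_sb")):
        sub = table[table[col]]
        n_pep = int((sub["target"] == "peptide").sum())
        n_hla = int((sub["target"] == "HLA").sum())
        out.loc[typ] = [n_pep, n_hla, n_pep + n_hla]
    return out


def compare_contact_tables(
    wt: pd.DataFrame,
    variant: pd.DataFrame,
    k: int = 10,
    preserved_min_contacts: int = 1,
) -> ContactComparison:
    """Compare two contact tables.

    Delta counts are variant minus wild type per contact type and target
    entity.  The preservation score asks how many of the wild type's
    ``k`` most-contacted pHLA residues (ranked by total contact rows,
    ties broken by residue order) still make at least
    ``preserved_min_contacts`` contacts in the variant.
    """
    delta = _counts_by_type_target(variant) - _counts_by_type_target(wt)

    def residue_totals(table: pd.DataFrame) -> pd.Series:
        if table.empty:
            return pd.Series(dtype=int)
        return table.groupby(["target", "target_chain", "target_resnum"]).size()

    wt_tot = residue_totals(wt)
    ranked = sorted(
        wt_tot.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1], kv[0][2])
    )
    top = [key for key, _ in ranked[:k]]
    var_tot = residue_totals(variant)
    preserved = sum(
        1 for key in top if int(var_tot.get(key, 0)) >= preserved_min_contacts
    )
    return ContactComparison(
        delta_counts=delta, preserved_top_contacts=preserved, k=k,
        top_wt_residues=top,
    )
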