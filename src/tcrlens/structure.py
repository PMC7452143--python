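"""Structures, chain-role annotation and sequence comparison for TCR-pHLA complexes.

A TCR-pHLA complex is represented as a flat, column-oriented
:class:`MolecularStructure` (one entry per atom) plus a
:class:`ComplexAnnotation` mapping chains to their biological roles
(TCR alpha/beta, HLA heavy chain, beta-2-microglobulin, peptide) and
recording variable-domain, CDR/HV4-loop and groove-helix residue ranges
in author (PDB) numbering.

Parsing is backed by :mod:`gemmi`; serialization writes fixed-column PDB
text so that structures round-trip through files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import gemmi
import yaml

__all__ = [
    "MolecularStructure",
    "ComplexAnnotation",
    "SequenceDifference",
    "Substitution",
    "ParseError",
    "AnnotationError",
    "AlignmentError",
    "ROLES",
    "LOOP_LABELS",
    "read_structure",
    "write_structure",
    "annotate_complex",
    "diff_sequences",
    "load_annotation_config",
]

ROLES = ("TCR_alpha", "TCR_beta", "HLA_heavy", "beta2m", "peptide")

#: CDR and hypervariable-4 loop labels; suffix a/b names the TCR chain.
LOOP_LABELS = ("CDR1a", "CDR2a", "CDR3a", "HV4a", "CDR1b", "CDR2b", "CDR3b", "HV4b")

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common variants mapped to their parent residue
    "MSE": "M", "HSD": "H", "HSE": "H", "HIE": "H", "HID": "H", "HIP": "H",
    "CYX": "C", "SEC": "U",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class AnnotationError(ValueError):
    """Raised when chain roles cannot be assigned unambiguously."""


class AlignmentError(ValueError):
    """Raised when two chains are too dissimilar to align reliably."""


@dataclass
class MolecularStructure:
    """Column-oriented atom table for one model of a structure.

    All array fields have one entry per atom, in file order.  Coordinates
    are in Angstrom, B-factors in Angstrom^2.
    """

    serial: np.ndarray            # int
    name: np.ndarray              # str, stripped atom names
    element: np.ndarray           # str, upper-case element symbols
    resname: np.ndarray           # str, 3-letter codes
    chain_id: np.ndarray          # str, single character
    resnum: np.ndarray            # int, author numbering
    icode: np.ndarray             # str, insertion code or ""
    coords: np.ndarray            # (n, 3) float
    occupancy: np.ndarray         # float
    b_factor: np.ndarray          # float
    is_hetero: np.ndarray         # bool, HETATM records
    header_resolution: Optional[float] = None
    entry_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    # -- basic selections -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.resname, sorted(WATER_NAMES))

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.isin(self.element, ["H", "D"])

    def heavy_mask(self, include_hetero: bool = False) -> np.ndarray:
        """Default analysis selection: heavy atoms, no waters, no hetero groups."""
        m = ~self.is_hydrogen & ~self.is_water
        if not include_hetero:
            m &= ~self.is_hetero
        return m

    def chain_mask(self, chain_ids: Iterable[str]) -> np.ndarray:
        return np.isin(self.chain_id, list(chain_ids))

    def subset(self, mask: np.ndarray) -> "MolecularStructure":
        idx = np.asarray(mask)
        return MolecularStructure(
            serial=self.serial[idx], name=self.name[idx], element=self.element[idx],
            resname=self.resname[idx], chain_id=self.chain_id[idx],
            resnum=self.resnum[idx], icode=self.icode[idx],
            coords=self.coords[idx], occupancy=self.occupancy[idx],
            b_factor=self.b_factor[idx], is_hetero=self.is_hetero[idx],
            header_resolution=self.header_resolution, entry_id=self.entry_id,
        )

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        out = replace(self)
        out.coords = np.array(coords, dtype=float)
        if out.coords.shape != self.coords.shape:
            raise ValueError("coordinate shape mismatch")
        return out

    # -- residue level ----------------------------------------------------

    def residue_ids(self, chain: str, polymer_only: bool = True) -> list[tuple[int, str]]:
        """Ordered unique (resnum, icode) of a chain, in file order."""
        m = self.chain_id == chain
        if polymer_only:
            m &= ~self.is_water & ~self.is_hetero
        seen: dict[tuple[int, str], None] = {}
        for rn, ic in zip(self.resnum[m], self.icode[m]):
            seen.setdefault((int(rn), str(ic)), None)
        return list(seen)

    def chain_sequence(self, chain: str) -> tuple[str, list[tuple[int, str]]]:
        """One-letter sequence of a chain's amino acids with residue ids."""
        ids = self.residue_ids(chain)
        m = self.chain_id == chain
        resname_of: dict[tuple[int, str], str] = {}
        for rn, ic, nm in zip(self.resnum[m], self.icode[m], self.resname[m]):
            resname_of.setdefault((int(rn), str(ic)), str(nm))
        seq, kept = [], []
        for rid in ids:
            one = AA3TO1.get(resname_of[rid])
            if one is not None:
                seq.append(one)
                kept.append(rid)
        return "".join(seq), kept

    def amino_acid_count(self, chain: str) -> int:
        return len(self.chain_sequence(chain)[0])

    def atom_index(self, chain: str, resnum: int, name: str, icode: str = "") -> int:
        m = (
            (self.chain_id == chain) & (self.resnum == resnum)
            & (self.icode == icode) & (self.name == name)
        )
        idx = np.flatnonzero(m)
        if len(idx) == 0:
            raise KeyError(f"no atom {chain}/{resnum}{icode}/{name}")
        return int(idx[0])

    def ca_indices(
        self, chain: str, residue_range: Optional[tuple[int, int]] = None
    ) -> np.ndarray:
        m = (self.chain_id == chain) & (self.name == "CA") & ~self.is_hydrogen
        m &= ~self.is_water
        if residue_range is not None:
            lo, hi = residue_range
            m &= (self.resnum >= lo) & (self.resnum <= hi)
        return np.flatnonzero(m)

    def polymer_chains(self) -> list[str]:
        """Chain ids with at least one standard amino acid, in file order."""
        out = []
        for ch in dict.fromkeys(self.chain_id.tolist()):
            if self.amino_acid_count(ch) > 0:
                out.append(ch)
        return out


@dataclass
class ComplexAnnotation:
    """Chain roles and residue-range annotations for a TCR-pHLA complex.

    Ranges are inclusive (start, end) in author numbering.  Loop labels use
    the ``CDR1a`` ... ``HV4b`` vocabulary; the a/b suffix ties a loop to
    the TCR alpha/beta chain.
    """

    role_map: dict[str, str]
    variable_domain_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    loop_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    groove_helix_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: conserved cysteine CA positions per TCR role, for the disulfide
    #: centroid rule of the crossing angle
    cys_positions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, role in self.role_map.items():
            if role not in ROLES:
                raise AnnotationError(f"unknown role {role!r} for chain {ch!r}")
        counts: dict[str, int] = {}
        for role in self.role_map.values():
            counts[role] = counts.get(role, 0) + 1
        dup = [r for r, c in counts.items() if c > 1]
        if dup:
            raise AnnotationError(f"roles assigned to more than one chain: {dup}")
        for lbl in self.loop_ranges:
            if lbl not in LOOP_LABELS:
                raise AnnotationError(f"unknown loop label {lbl!r}")
        # loops of one chain must not overlap
        for suffix in ("a", "b"):
            spans = sorted(
                rng for lbl, rng in self.loop_ranges.items() if lbl.endswith(suffix)
            )
            for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise AnnotationError(
                        f"overlapping loop ranges on chain {suffix}: "
                        f"({lo1},{hi1}) and ({lo2},{hi2})"
                    )

    def chain_of(self, role: str) -> str:
        for ch, r in self.role_map.items():
            if r == role:
                return ch
        raise AnnotationError(f"no chain with role {role!r}")

    def has_role(self, role: str) -> bool:
        return role in self.role_map.values()

    def loop_of(self, role: str, resnum: int) -> str:
        """Loop label containing a TCR residue, or ``"framework"``."""
        suffix = {"TCR_alpha": "a", "TCR_beta": "b"}.get(role)
        if suffix is None:
            return "framework"
        for lbl, (lo, hi) in self.loop_ranges.items():
            if lbl.endswith(suffix) and lo <= resnum <= hi:
                return lbl
        return "framework"

    def tcr_chains(self) -> list[str]:
        return [ch for ch, r in self.role_map.items() if r in ("TCR_alpha", "TCR_beta")]

    def phla_chains(self) -> list[str]:
        return [
            ch for ch, r in self.role_map.items()
            if r in ("HLA_heavy", "beta2m", "peptide")
        ]

    def to_dict(self) -> dict:
        return {
            "roles": dict(self.role_map),
            "variable_domains": {k: list(v) for k, v in self.variable_domain_ranges.items()},
            "loops": {k: list(v) for k, v in self.loop_ranges.items()},
            "groove_helices": {k: list(v) for k, v in self.groove_helix_ranges.items()},
            "disulfide_cys": {k: list(v) for k, v in self.cys_positions.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ComplexAnnotation":
        def pairs(m):
            return {k: (int(v[0]), int(v[1])) for k, v in (m or {}).items()}

        return cls(
            role_map=dict(d.get("roles", {})),
            variable_domain_ranges=pairs(d.get("variable_domains")),
            loop_ranges=pairs(d.get("loops")),
            groove_helix_ranges=pairs(d.get("groove_helices")),
            cys_positions=pairs(d.get("disulfide_cys")),
        )


@dataclass
class Substitution:
    chain_role: str
    position: int            # author numbering in the wild-type chain
    wt_residue: str          # one-letter
    variant_residue: str
    region: str              # loop label or "framework"

    @property
    def label(self) -> str:
        return f"{self.wt_residue}{self.position}{self.variant_residue}"


@dataclass
class SequenceDifference:
    """Residue-level differences between a wild-type and a variant TCR."""

    substitutions: list[Substitution]
    insertions: list[tuple[str, int, str]]   # (role, aligned position, residue)
    deletions: list[tuple[str, int, str]]
    identities: dict[str, float]             # per role, fraction of aligned columns

    def __len__(self) -> int:
        return len(self.substitutions)

    @property
    def is_identical(self) -> bool:
        return not (self.substitutions or self.insertions or self.deletions)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "chain_role": s.chain_role,
                    "position": s.position,
                    "wt": s.wt_residue,
                    "variant": s.variant_residue,
                    "region": s.region,
                }
                for s in self.substitutions
            ],
            columns=["chain_role", "position", "wt", "variant", "region"],
        )


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    """Cheap sanity check producing line-numbered errors for broken records."""
    text = path.read_text(errors="replace")
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}: malformed ATOM record at line {i}")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: malformed ATOM record at line {i}: {exc}"
                ) from None


def read_structure(
    path,
    altloc_policy: str = "highest_occupancy",
    model_index: int = 0,
) -> MolecularStructure:
    """Read one model of a PDB file into a :class:`MolecularStructure`.

    Parameters
    ----------
    path:
        Path to a PDB-format file.
    altloc_policy:
        ``"highest_occupancy"`` keeps, per (chain, residue, atom name), the
        alternate location with the largest occupancy (ties broken by altloc
        identifier order); ``"first"`` keeps the first conformer in file
        order; ``"all"`` keeps every conformer.
    model_index:
        Which MODEL of a multi-model file to load (0-based; default first).
    """
    path = Path(path)
    _prescan_pdb(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    if model_index >= len(st):
        raise ParseError(f"{path}: model index {model_index} out of range ({len(st)})")
    model = st[model_index]

    rows = []
    for chain in model:
        for res in chain:
            for atom in res:
                rows.append((
                    atom.serial,
                    atom.name,
                    atom.element.name.upper(),
                    res.name,
                    chain.name,
                    res.seqid.num,
                    (res.seqid.icode or " ").strip(),
                    (atom.pos.x, atom.pos.y, atom.pos.z),
                    atom.occ,
                    atom.b_iso,
                    res.het_flag == "H",
                    (atom.altloc or "").strip(),
                ))
    if not rows:
        raise ParseError(f"{path}: no atoms parsed")

    if altloc_policy not in ("highest_occupancy", "first", "all"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    if altloc_policy != "all":
        best: dict[tuple, tuple] = {}
        order: list[tuple] = []
        for row in rows:
            key = (row[4], row[5], row[6], row[1])  # chain, resnum, icode, name
            if key not in best:
                best[key] = row
                order.append(key)
            elif altloc_policy == "highest_occupancy":
                # higher occupancy wins; exact ties keep the earlier altloc id
                if row[8] > best[key][8]:
                    best[key] = row
        rows = [best[k] for k in order]

    res = st.resolution if st.resolution and st.resolution > 0 else None
    entry = (st.name or "").strip() or None
    return MolecularStructure(
        serial=np.array([r[0] for r in rows], dtype=int),
        name=np.array([r[1] for r in rows], dtype=object),
        element=np.array([r[2] for r in rows], dtype=object),
        resname=np.array([r[3] for r in rows], dtype=object),
        chain_id=np.array([r[4] for r in rows], dtype=object),
        resnum=np.array([r[5] for r in rows], dtype=int),
        icode=np.array([r[6] for r in rows], dtype=object),
        coords=np.array([r[7] for r in rows], dtype=float),
        occupancy=np.array([r[8] for r in rows], dtype=float),
        b_factor=np.array([r[9] for r in rows], dtype=float),
        is_hetero=np.array([r[10] for r in rows], dtype=bool),
        header_resolution=res,
        entry_id=entry,
    )


def write_structure(s: MolecularStructure, path=None) -> str:
    """Serialize a structure to fixed-column PDB text (optionally to a file)."""
    lines = []
    if s.header_resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {s.header_resolution:7.2f} ANGSTROMS."
        )
    for i in range(s.n_atoms):
        record = "HETATM" if s.is_hetero[i] else "ATOM  "
        name = s.name[i]
        # PDB column convention: 1-char elements start in column 14
        if len(name) < 4 and len(s.element[i]) == 1:
            name_field = f" {name:<3s}"
        else:
            name_field = f"{name:<4s}"
        x, y, z = s.coords[i]
        lines.append(
            f"{record}{int(s.serial[i]) % 100000:5d} {name_field} "
            f"{s.resname[i]:<3s} {s.chain_id[i]:1s}{int(s.resnum[i]):4d}"
            f"{s.icode[i] or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{s.occupancy[i]:6.2f}{s.b_factor[i]:6.2f}"
            f"          {s.element[i]:>2s}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_multi_model(structures: Sequence[MolecularStructure], path=None) -> str:
    """Serialize frames sharing one topology as a multi-model PDB."""
    chunks = []
    for i, s in enumerate(structures, start=1):
        body = write_structure(s).rsplit("END", 1)[0].rstrip("\n")
        chunks.append(f"MODEL     {i:4d}\n{body}\nENDMDL")
    text = "\n".join(chunks) + "\nEND\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

# chain-length windows (amino-acid counts) for the role heuristic
_LENGTH_WINDOWS = {
    "peptide": (8, 13),
    "beta2m": (95, 105),
    "HLA_heavy": (260, 290),
    # remaining two chains in this window are the TCR alpha/beta pair
    "TCR": (170, 260),
}


def annotate_complex(
    s: MolecularStructure,
    config: Optional[Mapping] = None,
    tcr_order: str = "alpha_first",
) -> ComplexAnnotation:
    """Assign chain roles and loop ranges.

    An explicit ``config`` mapping (see :func:`load_annotation_config`)
    always wins.  Without one, roles are assigned by amino-acid chain
    length: peptide 8-13, beta2m ~95-105, HLA heavy chain ~260-290, and the
    remaining two mid-size chains become TCR alpha/beta in declared file
    order (``tcr_order="alpha_first"``) or reversed (``"beta_first"``).
    Loop and domain ranges are never guessed: without a config only roles
    are annotated.
    """
    if config:
        ann = ComplexAnnotation.from_dict(config)
        known = set(ann.role_map)
        missing = [ch for ch in ann.role_map if ch not in set(s.chain_id)]
        if missing:
            raise AnnotationError(f"config names absent chains: {missing}")
        if len(known) < 4:
            raise AnnotationError("config must assign at least 4 chains")
        return ann

    chains = s.polymer_chains()
    if len(chains) < 4:
        raise AnnotationError(
            f"need >=4 polymer chains for the length heuristic, got {len(chains)}: "
            f"{chains}; supply an explicit config"
        )
    lengths = {ch: s.amino_acid_count(ch) for ch in chains}

    def in_window(n: int, key: str) -> bool:
        lo, hi = _LENGTH_WINDOWS[key]
        return lo <= n <= hi

    role_map: dict[str, str] = {}
    for role in ("peptide", "beta2m", "HLA_heavy"):
        cand = [ch for ch in chains if ch not in role_map and in_window(lengths[ch], role)]
        if len(cand) != 1:
            raise AnnotationError(
                f"ambiguous {role} assignment, candidates {cand} "
                f"(chain lengths {lengths}); supply an explicit config"
            )
        role_map[cand[0]] = role
    rest = [ch for ch in chains if ch not in role_map]
    rest = [ch for ch in rest if in_window(lengths[ch], "TCR")]
    if len(rest) != 2:
        raise AnnotationError(
            f"cannot identify the TCR chain pair among {rest} "
            f"(chain lengths {lengths}); supply an explicit config"
        )
    if tcr_order == "beta_first":
        rest = rest[::-1]
    elif tcr_order != "alpha_first":
        raise ValueError(f"unknown tcr_order {tcr_order!r}")
    role_map[rest[0]] = "TCR_alpha"
    role_map[rest[1]] = "TCR_beta"
    # invert to chain->role ordering consistent with file order
    ordered = {ch: role_map[ch] for ch in chains if ch in role_map}
    return ComplexAnnotation(role_map=ordered)


def load_annotation_config(path) -> dict:
    """Load an annotation config (YAML) as a plain mapping.

    Schema (all ranges inclusive, author numbering)::

        roles: {A: HLA_heavy, B: beta2m, C: peptide, D: TCR_alpha, E: TCR_beta}
        variable_domains: {TCR_alpha: [1, 110], TCR_beta: [1, 115]}
        loops: {CDR1a: [24, 32], CDR2a: [48, 56], CDR3a: [90, 100], ...}
        groove_helices: {alpha1: [50, 84], alpha2: [138, 180]}
        disulfide_cys: {TCR_alpha: [23, 104], TCR_beta: [23, 104]}
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "roles" not in data:
        raise AnnotationError(f"{path}: annotation config must define 'roles'")
    return data


# ---------------------------------------------------------------------------
# Sequence comparison
# ---------------------------------------------------------------------------

def _align(seq1: str, seq2: str):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    return aligner.align(seq1, seq2)[0]


def diff_sequences(
    wt: MolecularStructure,
    wt_annotation: ComplexAnnotation,
    variant: MolecularStructure,
    variant_annotation: ComplexAnnotation,
    roles: Sequence[str] = ("TCR_alpha", "TCR_beta"),
    min_identity: float = 0.70,
) -> SequenceDifference:
    """List residue substitutions between matched chains of two complexes.

    Chains are paired by role, globally aligned, and aligned columns with
    differing residues are reported as substitutions (in wild-type author
    numbering, labelled with the wild-type loop region).  Insertions and
    deletions are reported separately and never counted as substitutions.
    An alignment identity below ``min_identity`` raises
    :class:`AlignmentError` (likely chain mispairing).
    """
    subs: list[Substitution] = []
    ins: list[tuple[str, int, str]] = []
    dels: list[tuple[str, int, str]] = []
    identities: dict[str, float] = {}

    for role in roles:
        ch_wt = wt_annotation.chain_of(role)
        ch_var = variant_annotation.chain_of(role)
        seq_wt, ids_wt = wt.chain_sequence(ch_wt)
        seq_var, ids_var = variant.chain_sequence(ch_var)
        if not seq_wt or not seq_var:
            raise AlignmentError(f"empty sequence for role {role}")
        aln = _align(seq_wt, seq_var)
        i = j = 0
        matched = same = 0
        for (s1, e1), (s2, e2) in zip(*aln.aligned):
            # gap in variant before this block -> deletions
            while i < s1:
                dels.append((role, ids_wt[i][0], seq_wt[i]))
                i += 1
            while j < s2:
                ins.append((role, ids_var[j][0], seq_var[j]))
                j += 1
            for k in range(e1 - s1):
                a, b = seq_wt[s1 + k], seq_var[s2 + k]
                matched += 1
                if a == b:
                    same += 1
                else:
                    pos = ids_wt[s1 + k][0]
                    subs.append(Substitution(
                        chain_role=role, position=pos, wt_residue=a,
                        variant_residue=b,
                        region=wt_annotation.loop_of(role, pos),
                    ))
            i, j = e1, e2
        while i < len(seq_wt):
            dels.append((role, ids_wt[i][0], seq_wt[i]))
            i += 1
        while j < len(seq_var):
            ins.append((role, ids_var[j][0], seq_var[j]))
            j += 1
        identity = same / matched if matched else 0.0
        identities[role] = identity
        if identity < min_identity:
            raise AlignmentError(
                f"alignment identity {identity:.2f} for role {role} below "
                f"{min_identity:.2f}; chains are likely mispaired"
            )
    return SequenceDifference(
        substitutions=subs, insertions=ins, deletions=dels, identities=identities
    )
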