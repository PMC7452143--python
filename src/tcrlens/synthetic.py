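"""Seeded generators for toy TCR-pHLA fixtures.

The toy complex is a C-alpha-plus-probe-atom model, not a physically
realistic protein: a peptide trace lies along the lab x axis between two
pseudo-helix traces (the groove), and two pseudo-variable-domain point
clouds float above it.  The construction places the domain centroids so
that the crossing angle and docking footprint are exact by design, and
plants individual interface contacts at requested distances, which makes
every downstream geometric or statistical metric checkable against its
construction value.  Ensembles add per-residue isotropic Gaussian jitter
(RMSF = sigma * sqrt(3)) and optional two-state hydrogen-bond switching
with a planted occupancy.

All randomness flows through one ``numpy.random.default_rng(seed)``;
generation is bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .energetics import ForceFieldParameters
from .structure import ComplexAnnotation, MolecularStructure

__all__ = [
    "ToyComplexSpec",
    "PlantedContact",
    "EnsembleSpec",
    "HBondEvent",
    "make_toy_complex",
    "make_ensemble",
    "make_toy_parameters",
    "make_toy_binding_system",
]

CA_SPACING = 3.8      # A, consecutive C-alpha spacing of traces
HELIX_OFFSET = 9.0    # A, helix traces at y = +/- this
TCR_HEIGHT = 25.0     # A, variable-domain centroids above the groove plane
DOMAIN_SEP = 20.0     # A, Valpha -> Vbeta centroid separation

# residue layout of the toy complex (author numbering, inclusive)
PEPTIDE_CHAIN, HLA_CHAIN, B2M_CHAIN, TCRA_CHAIN, TCRB_CHAIN = "C", "A", "B", "D", "E"
HELIX1_RANGE = (57, 84)
HELIX2_RANGE = (138, 180)
HLA_LENGTH = 276
B2M_LENGTH = 99
TCRA_LENGTH = 200
TCRB_LENGTH = 240
VDOM_A = (1, 110)
VDOM_B = (1, 115)
CYS_A = (23, 104)
CYS_B = (23, 104)
PROBE_RESNUM_START = 150   # planted-contact probe residues, outside V domains

_FILLER_SEQ = "ARNDCQEGHILKMFPSTWYV"


class SyntheticError(ValueError):
    pass


@dataclass
class PlantedContact:
    """One interface contact realized at an exact distance.

    ``kind`` selects the chemistry: ``"hb"`` plants a backbone-N donor over
    a backbone-O acceptor (typed vdW+HB), ``"vdw"`` an apolar carbon pair
    (vdW only), ``"sb"`` a Lys NZ over a Glu OE1 (vdW+HB+SB at typical
    distances).  ``target`` is ``"peptide"`` or ``"hla"``;
    ``target_index`` picks the host residue (0-based along the peptide or
    the alpha1 helix).  ``tcr_chain`` must be the toy TCR alpha ("D") or
    beta ("E") chain.
    """

    kind: str = "hb"
    distance: float = 2.9
    target: str = "peptide"
    target_index: int = 0
    tcr_chain: str = TCRA_CHAIN

    def __post_init__(self) -> None:
        if self.kind not in ("hb", "vdw", "sb"):
            raise SyntheticError(f"unknown contact kind {self.kind!r}")
        if self.target not in ("peptide", "hla"):
            raise SyntheticError(f"unknown target {self.target!r}")
        if self.tcr_chain not in (TCRA_CHAIN, TCRB_CHAIN):
            raise SyntheticError(f"tcr_chain must be {TCRA_CHAIN} or {TCRB_CHAIN}")
        if self.distance <= 0:
            raise SyntheticError("contact distance must be positive")


@dataclass
class ToyComplexSpec:
    """Construction parameters of a toy complex."""

    crossing_angle: float = 45.0        # degrees, [0, 180)
    footprint_offset: tuple[float, float] = (0.0, 0.0)   # (x, y) A
    peptide_length: int = 9
    planted_contacts: list[PlantedContact] = field(default_factory=list)
    seed: int = 0
    jitter: float = 1.0                 # A, domain point-cloud spread

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossing_angle < 180.0:
            raise SyntheticError("crossing angle must be in [0, 180)")
        if self.peptide_length < 8:
            raise SyntheticError("peptide length must be >= 8")


def _trace(x_positions, y, z):
    return np.column_stack([
        np.asarray(x_positions, dtype=float),
        np.full(len(x_positions), float(y)),
        np.full(len(x_positions), float(z)),
    ])


def _centered_xs(n: int) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * CA_SPACING


class _Builder:
    """Accumulates atom rows for a MolecularStructure."""

    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def add(self, name, element, resname, chain, resnum, xyz):
        self.rows.append((
            len(self.rows) + 1, name, element, resname, chain, int(resnum),
            "", tuple(float(v) for v in xyz), 1.0, 0.0, False,
        ))

    def build(self, entry_id: Optional[str] = None) -> MolecularStructure:
        r = self.rows
        return MolecularStructure(
            serial=np.array([a[0] for a in r], dtype=int),
            name=np.array([a[1] for a in r], dtype=object),
            element=np.array([a[2] for a in r], dtype=object),
            resname=np.array([a[3] for a in r], dtype=object),
            chain_id=np.array([a[4] for a in r], dtype=object),
            resnum=np.array([a[5] for a in r], dtype=int),
            icode=np.array([a[6] for a in r], dtype=object),
            coords=np.array([a[7] for a in r], dtype=float),
            occupancy=np.array([a[8] for a in r], dtype=float),
            b_factor=np.array([a[9] for a in r], dtype=float),
            is_hetero=np.array([a[10] for a in r], dtype=bool),
            entry_id=entry_id,
        )


def _add_chain_trace(b: _Builder, chain: str, coords: np.ndarray,
                     resnum_start: int = 1, cys_at: Sequence[int] = ()) -> None:
    for i, xyz in enumerate(coords):
        rn = resnum_start + i
        resname = "CYS" if rn in cys_at else _FILLER_SEQ[i % len(_FILLER_SEQ)]
        if len(resname) == 1:
            resname = {
                "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
                "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
                "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
                "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
            }[resname]
        b.add("CA", "C", resname, chain, rn, xyz)


def _domain_cloud(rng: np.random.Generator, centroid: np.ndarray, n: int,
                  jitter: float) -> np.ndarray:
    """Point cloud whose empirical mean equals the centroid exactly."""
    pts = rng.normal(scale=jitter, size=(n, 3))
    pts -= pts.mean(axis=0)
    return pts + centroid


def make_toy_complex(
    spec: ToyComplexSpec,
) -> tuple[MolecularStructure, ComplexAnnotation]:
    """Build a toy complex whose geometry metrics equal the spec by
    construction (round-trip oracle for the geometry module)."""
    rng = np.random.default_rng(spec.seed)
    b = _Builder()

    # HLA heavy chain: two groove helices plus a filler slab below
    hla = np.zeros((HLA_LENGTH, 3))
    for rn in range(1, HLA_LENGTH + 1):
        i = rn - 1
        if HELIX1_RANGE[0] <= rn <= HELIX1_RANGE[1]:
            n = HELIX1_RANGE[1] - HELIX1_RANGE[0] + 1
            hla[i] = [_centered_xs(n)[rn - HELIX1_RANGE[0]], HELIX_OFFSET, 0.0]
        elif HELIX2_RANGE[0] <= rn <= HELIX2_RANGE[1]:
            n = HELIX2_RANGE[1] - HELIX2_RANGE[0] + 1
            hla[i] = [_centered_xs(n)[rn - HELIX2_RANGE[0]], -HELIX_OFFSET, 0.0]
        else:
            # filler grid well below the groove plane
            row, col = divmod(i, 20)
            hla[i] = [(col - 9.5) * CA_SPACING, (row % 5 - 2) * CA_SPACING,
                      -18.0 - (row // 5) * CA_SPACING]
    _add_chain_trace(b, HLA_CHAIN, hla)

    # beta-2-microglobulin: slab further below
    b2m = np.zeros((B2M_LENGTH, 3))
    for i in range(B2M_LENGTH):
        row, col = divmod(i, 12)
        b2m[i] = [(col - 5.5) * CA_SPACING, (row % 4 - 1.5) * CA_SPACING,
                  -45.0 - (row // 4) * CA_SPACING]
    _add_chain_trace(b, B2M_CHAIN, b2m)

    # peptide along x, centered on the origin
    pep = _trace(_centered_xs(spec.peptide_length), 0.0, 0.0)
    _add_chain_trace(b, PEPTIDE_CHAIN, pep)

    # variable-domain centroids from the requested angle and footprint
    phi = np.radians(spec.crossing_angle)
    u = np.array([np.cos(phi), np.sin(phi), 0.0])
    fx, fy = spec.footprint_offset
    n_a = VDOM_A[1] - VDOM_A[0] + 1
    n_b = VDOM_B[1] - VDOM_B[0] + 1
    combined = np.array([fx, fy, TCR_HEIGHT])
    cen_a = combined - (n_b / (n_a + n_b)) * DOMAIN_SEP * u
    cen_b = combined + (n_a / (n_a + n_b)) * DOMAIN_SEP * u

    def tcr_chain(chain, length, vdom, cys, centroid):
        coords = np.zeros((length, 3))
        lo, hi = vdom
        nv = hi - lo + 1
        cloud = _domain_cloud(rng, centroid, nv, spec.jitter)
        # conserved "cysteines" placed symmetrically about the centroid so
        # the disulfide and whole-domain centroid rules agree exactly
        delta = np.array([1.5, -1.0, 0.8])
        cloud[cys[0] - lo] = centroid + delta
        cloud[cys[1] - lo] = centroid - delta
        inner = np.delete(np.arange(nv), [cys[0] - lo, cys[1] - lo])
        # re-center via the non-cysteine atoms so both centroid rules are exact
        cloud[inner] -= (cloud.mean(axis=0) - centroid) * (nv / len(inner))
        coords[lo - 1: hi] = cloud
        # constant-domain filler: slab above the variable domains
        n_fill = length - nv
        for j in range(n_fill):
            row, col = divmod(j, 15)
            coords[hi + j] = [(col - 7) * CA_SPACING,
                              (row % 4 - 1.5) * CA_SPACING + centroid[1],
                              TCR_HEIGHT + 22.0 + row * 2.0]
        return coords

    coords_a = tcr_chain(TCRA_CHAIN, TCRA_LENGTH, VDOM_A, CYS_A, cen_a)
    coords_b = tcr_chain(TCRB_CHAIN, TCRB_LENGTH, VDOM_B, CYS_B, cen_b)
    _add_chain_trace(b, TCRA_CHAIN, coords_a, cys_at=CYS_A)
    _add_chain_trace(b, TCRB_CHAIN, coords_b, cys_at=CYS_B)

    # planted contacts: probe atoms on dedicated TCR residues above the
    # target atom; anchor atoms are added to the host residue
    for k, pc in enumerate(spec.planted_contacts):
        if pc.target == "peptide":
            if pc.target_index >= spec.peptide_length:
                raise SyntheticError("planted contact beyond peptide length")
            anchor_xy = pep[pc.target_index, :2]
            host = (PEPTIDE_CHAIN, pc.target_index + 1)
        else:
            n1 = HELIX1_RANGE[1] - HELIX1_RANGE[0] + 1
            if pc.target_index >= n1:
                raise SyntheticError("planted contact beyond alpha1 helix")
            anchor_xy = np.array([_centered_xs(n1)[pc.target_index], HELIX_OFFSET])
            host = (HLA_CHAIN, HELIX1_RANGE[0] + pc.target_index)
        lift = 1.5   # anchor raised off the trace to avoid trace contacts
        anchor = np.array([anchor_xy[0], anchor_xy[1], lift])
        probe = anchor + np.array([0.0, 0.0, pc.distance])
        if pc.distance + lift > 12.0:
            raise SyntheticError("planted contact distance too large to realize")
        if pc.kind == "hb":
            anchor_atom, anchor_res = ("O", "O"), "GLY"
            probe_atom, probe_res = ("N", "N"), "GLY"
        elif pc.kind == "vdw":
            anchor_atom, anchor_res = ("CB", "C"), "ALA"
            probe_atom, probe_res = ("CB", "C"), "ALA"
        else:  # salt bridge
            anchor_atom, anchor_res = ("OE1", "O"), "GLU"
            probe_atom, probe_res = ("NZ", "N"), "LYS"
        # host residue keeps its identity unless the contact needs chemistry
        host_resname = anchor_res if pc.kind != "vdw" else "ALA"
        b.add(anchor_atom[0], anchor_atom[1], host_resname, host[0], host[1], anchor)
        b.add(probe_atom[0], probe_atom[1], probe_res, pc.tcr_chain,
              PROBE_RESNUM_START + k, probe)

    s = b.build(entry_id=f"TOY{spec.seed:04d}")
    # planted anchor atoms change the host residue name seen by the contact
    # typer; rewrite the CA of the host residue to match
    for k, pc in enumerate(spec.planted_contacts):
        if pc.kind == "vdw":
            continue
        host = ((PEPTIDE_CHAIN, pc.target_index + 1) if pc.target == "peptide"
                else (HLA_CHAIN, HELIX1_RANGE[0] + pc.target_index))
        resname = "GLY" if pc.kind == "hb" else "GLU"
        m = (s.chain_id == host[0]) & (s.resnum == host[1])
        s.resname[m] = resname

    annotation = ComplexAnnotation(
        role_map={
            HLA_CHAIN: "HLA_heavy", B2M_CHAIN: "beta2m",
            PEPTIDE_CHAIN: "peptide", TCRA_CHAIN: "TCR_alpha",
            TCRB_CHAIN: "TCR_beta",
        },
        variable_domain_ranges={"TCR_alpha": VDOM_A, "TCR_beta": VDOM_B},
        loop_ranges={
            "CDR1a": (24, 32), "CDR2a": (48, 56), "CDR3a": (90, 100),
            "HV4a": (65, 72),
            "CDR1b": (24, 32), "CDR2b": (48, 56), "CDR3b": (90, 100),
            "HV4b": (65, 72),
        },
        groove_helix_ranges={"alpha1": HELIX1_RANGE, "alpha2": HELIX2_RANGE},
        cys_positions={"TCR_alpha": CYS_A, "TCR_beta": CYS_B},
    )
    return s, annotation


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

@dataclass
class HBondEvent:
    """Two-state hydrogen bond with planted occupancy.

    In each frame the donor atom is placed along the base donor-acceptor
    axis at ``bound_distance`` with probability ``p_bound``, otherwise at
    ``unbound_distance`` (the donor atom receives no jitter).
    """

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    p_bound: float = 0.7
    bound_distance: float = 2.9
    unbound_distance: float = 4.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bound <= 1.0:
            raise SyntheticError("p_bound must be in [0, 1]")


@dataclass
class EnsembleSpec:
    """Replica-ensemble generation parameters."""

    replicas: int = 10
    frames: int = 100
    sigma_profile: object = 0.3    # scalar or per-residue array (A)
    hb_events: list[HBondEvent] = field(default_factory=list)
    seed: int = 0
    frame_interval_ns: float = 0.1
    burn_in_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.replicas < 1 or self.frames < 1:
            raise SyntheticError("need >= 1 replica and >= 1 frame")


def _per_atom_sigma(base: MolecularStructure, sigma_profile) -> np.ndarray:
    """Broadcast a per-residue sigma profile to atoms (file residue order)."""
    residue_keys: list[tuple] = []
    atom_res_index = np.empty(base.n_atoms, dtype=int)
    seen: dict[tuple, int] = {}
    for i in range(base.n_atoms):
        key = (str(base.chain_id[i]), int(base.resnum[i]), str(base.icode[i]))
        if key not in seen:
            seen[key] = len(residue_keys)
            residue_keys.append(key)
        atom_res_index[i] = seen[key]
    if np.isscalar(sigma_profile):
        res_sigma = np.full(len(residue_keys), float(sigma_profile))
    else:
        res_sigma = np.asarray(sigma_profile, dtype=float)
        if len(res_sigma) != len(residue_keys):
            raise SyntheticError(
                f"sigma_profile length {len(res_sigma)} != residue count "
                f"{len(residue_keys)}"
            )
    if np.any(res_sigma < 0):
        raise SyntheticError("sigma_profile must be >= 0")
    return res_sigma[atom_res_index]


def make_ensemble(base: MolecularStructure, spec: EnsembleSpec):
    """Gaussian-jitter replica ensemble around a base structure."""
    from .ensemble import TrajectoryEnsemble

    rng = np.random.default_rng(spec.seed)
    sigma = _per_atom_sigma(base, spec.sigma_profile)
    hb_idx = [
        (base.atom_index(*ev.donor), base.atom_index(*ev.acceptor))
        for ev in spec.hb_events
    ]
    replicas = []
    for _ in range(spec.replicas):
        noise = rng.normal(size=(spec.frames, base.n_atoms, 3)) * sigma[None, :, None]
        frames = base.coords[None, :, :] + noise
        for (di, ai), ev in zip(hb_idx, spec.hb_events):
            states = rng.random(spec.frames) < ev.p_bound
            dist = np.where(states, ev.bound_distance, ev.unbound_distance)
            axis = base.coords[di] - base.coords[ai]
            axis = axis / np.linalg.norm(axis)
            frames[:, di, :] = frames[:, ai, :] + dist[:, None] * axis[None, :]
        replicas.append(frames)
    return TrajectoryEnsemble(
        topology=base, replicas=replicas,
        frame_interval_ns=spec.frame_interval_ns,
        burn_in_fraction=spec.burn_in_fraction,
    )


# ---------------------------------------------------------------------------
# Toy force-field parameters
# ---------------------------------------------------------------------------

def make_toy_parameters(
    s: MolecularStructure,
    scheme: str = "neutral",
    seed: int = 0,
) -> ForceFieldParameters:
    """Deterministic per-atom parameter tables for energetics tests.

    Schemes: ``"neutral"`` (all charges zero), ``"single_ion"`` (unit
    charge on the first atom only), ``"random"`` (seeded small random
    charges), ``"charged_probes"`` (unit charges of alternating sign on
    planted N/O probe atoms).
    """
    n = s.n_atoms
    rng = np.random.default_rng(seed)
    charge = np.zeros(n)
    if scheme == "neutral":
        pass
    elif scheme == "single_ion":
        charge[0] = 1.0
    elif scheme == "random":
        charge = rng.uniform(-0.5, 0.5, size=n)
    elif scheme == "charged_probes":
        for i in range(n):
            if s.name[i] == "NZ" or (s.name[i] == "N" and s.resname[i] == "GLY"):
                charge[i] = 1.0
            elif s.name[i] in ("OE1", "O") and s.resname[i] in ("GLU", "GLY"):
                charge[i] = -1.0
    else:
        raise SyntheticError(f"unknown parameter scheme {scheme!r}")
    is_n = np.array([str(e).upper() == "N" for e in s.element])
    is_o = np.array([str(e).upper() == "O" for e in s.element])
    rmin_half = np.where(is_n, 1.824, np.where(is_o, 1.6612, 1.908))
    epsilon = np.where(is_n, 0.17, np.where(is_o, 0.21, 0.1094))
    born = np.where(is_n, 1.55, np.where(is_o, 1.50, 1.70))
    table = pd.DataFrame({
        "chain": s.chain_id.astype(str),
        "resnum": s.resnum.astype(int),
        "atom": s.name.astype(str),
        "charge": charge,
        "rmin_half": rmin_half,
        "epsilon": epsilon,
        "born_radius": born,
        "screen": np.full(n, 0.8),
    })
    return ForceFieldParameters(table=table)


def make_toy_binding_system(
    n_per_side: int = 12,
    seed: int = 0,
    charge_scale: float = 0.3,
    separation: float = 6.0,
):
    """Small random two-chain "dimer" with full parameters for MM/GBSA
    bookkeeping tests: a TCR-role chain of probe atoms above a
    peptide-role chain.  Returns (structure, annotation, parameters)."""
    rng = np.random.default_rng(seed)
    b = _Builder()
    elements = ["C", "N", "O"]
    # peptide-role chain: 9 residues, atoms scattered in a slab near z=0
    for i in range(n_per_side):
        xyz = rng.uniform(-6, 6, size=3) * np.array([1, 1, 0.3])
        el = elements[int(rng.integers(3))]
        b.add("CA" if el == "C" else ("N" if el == "N" else "O"), el,
              "ALA", "C", i + 1, xyz)
    # TCR-role chain above (one atom per residue keeps atom ids unique)
    for i in range(n_per_side):
        xyz = rng.uniform(-6, 6, size=3) * np.array([1, 1, 0.3])
        xyz[2] += separation
        el = elements[int(rng.integers(3))]
        b.add("CA" if el == "C" else ("N" if el == "N" else "O"), el,
              "ALA", "D", i + 1, xyz)
    s = b.build(entry_id=f"DIM{seed:04d}")
    ann = ComplexAnnotation(role_map={"C": "peptide", "D": "TCR_alpha"})
    params = make_toy_parameters(s, scheme="random", seed=seed)
    params.table["charge"] = rng.uniform(-1, 1, size=s.n_atoms) * charge_scale
    params = ForceFieldParameters(table=params.table)
    return s, ann, params
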