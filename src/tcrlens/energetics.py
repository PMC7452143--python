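"""Simplified single-trajectory MM/GBSA binding-energy estimator.

The binding free energy of a TCR-pHLA snapshot is estimated as

    dG_bind = E_vdw + E_elec + dG_polar + dG_nonpolar

where E_vdw / E_elec are the pairwise Lennard-Jones and Coulomb
interaction energies between the TCR and pHLA atom sets (internal terms
cancel exactly in the single-trajectory convention), dG_polar is the
generalized-Born solvation change on binding (OBC-II rescaled
Hawkins-Cramer-Truhlar descreening, Debye-Hueckel salt screening), and
dG_nonpolar = gamma * dSASA.  Averaging over snapshots gives the
estimate; per-residue decomposition splits every pairwise term half-half
between the partner residues so that residue contributions sum exactly
to the total.  Entropy is not modelled: the contract is relative ranking
of similar complexes, not absolute affinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure import ComplexAnnotation, MolecularStructure
from .surface import compute_sasa

__all__ = [
    "EnergeticsConfig",
    "ForceFieldParameters",
    "BindingEnergyEstimate",
    "PerResidueEnergyTable",
    "EnergyClassification",
    "AffinityRecord",
    "mm_interaction_energy",
    "effective_born_radii",
    "gb_polar_energy",
    "nonpolar_energy",
    "mmgbsa_binding",
    "decompose_per_residue",
    "classify_ddg",
    "kd_to_dg",
    "fold_change",
    "ddg_exp",
    "rank_correlation",
    "read_parameter_table",
    "read_affinity_csv",
]


class EnergeticsError(ValueError):
    pass


@dataclass
class EnergeticsConfig:
    """Physical constants and model settings (kcal, mol, Angstrom, e)."""

    eps_in: float = 1.0
    eps_out: float = 78.5
    coulomb_constant: float = 332.0637      # kcal*A/(mol*e^2)
    salt_molar: float = 0.150
    gamma_np: float = 0.0072                # kcal/(mol*A^2)
    beta_np: float = 0.0                    # kcal/mol
    temperature: float = 298.15
    gas_constant: float = 1.9872e-3         # kcal/(mol*K)
    snapshot_count: int = 300
    # GB (OBC-II) machinery
    born_offset: float = 0.09               # A, intrinsic-radius offset
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85
    # SASA quadrature used inside the nonpolar term
    probe_radius: float = 1.4
    sasa_points: int = 240

    def __post_init__(self) -> None:
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise EnergeticsError("dielectrics must be positive")
        if self.salt_molar < 0:
            raise EnergeticsError("salt concentration must be >= 0")

    @property
    def kappa(self) -> float:
        """Debye screening parameter (A^-1) from the salt concentration."""
        if self.salt_molar == 0:
            return 0.0
        return 50.29216 * np.sqrt(self.salt_molar / (self.eps_out * self.temperature))

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass
class ForceFieldParameters:
    """Per-atom charges, Lennard-Jones and generalized-Born parameters.

    ``table`` is keyed by (chain, resnum, atom name); :meth:`align`
    produces arrays ordered like a structure's atoms.
    """

    table: pd.DataFrame   # chain, resnum, atom, charge, rmin_half, epsilon,
                          # born_radius, screen

    REQUIRED = ["chain", "resnum", "atom", "charge", "rmin_half", "epsilon",
                "born_radius", "screen"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise EnergeticsError(f"parameter table lacks columns {missing}")
        self._lookup = {
            (str(r.chain), int(r.resnum), str(r.atom)): i
            for i, r in enumerate(self.table.itertuples(index=False))
        }

    def align(self, s: MolecularStructure, idx: np.ndarray) -> dict[str, np.ndarray]:
        rows = []
        for i in idx:
            key = (str(s.chain_id[i]), int(s.resnum[i]), str(s.name[i]))
            j = self._lookup.get(key)
            if j is None:
                raise EnergeticsError(f"no parameters for atom {key}")
            rows.append(j)
        sub = self.table.iloc[rows]
        return {
            "charge": sub["charge"].to_numpy(float),
            "rmin_half": sub["rmin_half"].to_numpy(float),
            "epsilon": sub["epsilon"].to_numpy(float),
            "born_radius": sub["born_radius"].to_numpy(float),
            "screen": sub["screen"].to_numpy(float),
        }

    def write(self, path) -> None:
        self.table.to_csv(path, sep=" ", index=False)


def read_parameter_table(path) -> ForceFieldParameters:
    """Read the documented whitespace-delimited per-atom parameter table."""
    df = pd.read_csv(path, sep=r"\s+")
    return ForceFieldParameters(table=df)


# ---------------------------------------------------------------------------
# Molecular-mechanics interaction terms
# ---------------------------------------------------------------------------

def mm_interaction_energy(
    coords: np.ndarray,
    charge: np.ndarray,
    rmin_half: np.ndarray,
    epsilon: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    config: EnergeticsConfig | None = None,
    per_atom: bool = False,
):
    """Pairwise LJ and Coulomb energy between two disjoint atom sets.

    Gas-phase sums with no cutoff.  Lorentz-Berthelot-style combination:
    rmin_ij = rmin_half_i + rmin_half_j, eps_ij = sqrt(eps_i eps_j).
    Returns (E_vdw, E_elec) in kcal/mol, plus per-atom half-shares of both
    terms when ``per_atom`` is set.
    """
    config = config or EnergeticsConfig()
    xyz = np.asarray(coords, dtype=float)
    d = np.linalg.norm(xyz[idx_a][:, None, :] - xyz[idx_b][None, :, :], axis=2)
    if d.size and d.min() < 0.1:
        i, j = np.unravel_index(int(d.argmin()), d.shape)
        raise EnergeticsError(
            f"overlapping atoms (r={d.min():.3f} A) between atom indices "
            f"{idx_a[i]} and {idx_b[j]}"
        )
    q = config.coulomb_constant / config.eps_in
    e_elec_pair = q * np.outer(charge[idx_a], charge[idx_b]) / d
    rmin = rmin_half[idx_a][:, None] + rmin_half[idx_b][None, :]
    eps = np.sqrt(np.outer(epsilon[idx_a], epsilon[idx_b]))
    sr6 = (rmin / d) ** 6
    e_vdw_pair = eps * (sr6 * sr6 - 2.0 * sr6)
    e_vdw, e_elec = float(e_vdw_pair.sum()), float(e_elec_pair.sum())
    if not per_atom:
        return e_vdw, e_elec
    n = len(xyz)
    vdw_share, elec_share = np.zeros(n), np.zeros(n)
    vdw_share[idx_a] = 0.5 * e_vdw_pair.sum(axis=1)
    vdw_share[idx_b] = 0.5 * e_vdw_pair.sum(axis=0)
    elec_share[idx_a] = 0.5 * e_elec_pair.sum(axis=1)
    elec_share[idx_b] = 0.5 * e_elec_pair.sum(axis=0)
    return e_vdw, e_elec, vdw_share, elec_share


# ---------------------------------------------------------------------------
# Generalized Born
# ---------------------------------------------------------------------------

def effective_born_radii(
    coords: np.ndarray,
    born_radius: np.ndarray,
    screen: np.ndarray,
    config: EnergeticsConfig | None = None,
) -> np.ndarray:
    """OBC-II effective Born radii via pairwise HCT descreening.

    Intrinsic radii are offset-reduced (rho = R - offset); the pairwise
    descreening integral I is accumulated over scaled neighbour spheres
    and rescaled through the OBC tanh form
    R_eff = 1 / (1/rho - tanh(a*psi - b*psi^2 + g*psi^3) / R).
    """
    config = config or EnergeticsConfig()
    xyz = np.asarray(coords, dtype=float)
    R = np.asarray(born_radius, dtype=float)
    if np.any(R <= config.born_offset):
        bad = int(np.argmax(R <= config.born_offset))
        raise EnergeticsError(
            f"born radius {R[bad]} A of atom {bad} not above the offset "
            f"{config.born_offset} A"
        )
    rho = R - config.born_offset
    sr = np.asarray(screen, dtype=float) * rho
    n = len(xyz)
    if n == 1:
        return rho.copy()
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)

    or1 = rho[:, None]            # descreened atom i
    sr2 = sr[None, :]             # scaled neighbour j
    U = d + sr2
    L = np.maximum(or1, np.abs(d - sr2))
    with np.errstate(divide="ignore", invalid="ignore"):
        I = 0.5 * (
            1.0 / L - 1.0 / U
            + 0.25 * (d - sr2 ** 2 / d) * (1.0 / U ** 2 - 1.0 / L ** 2)
            + 0.5 * np.log(L / U) / d
        )
        # atom i fully engulfed by neighbour j's scaled sphere
        engulfed = sr2 - d > or1
        I = I + np.where(engulfed, 2.0 * (1.0 / or1 - 1.0 / L), 0.0)
    I = np.where(d + sr2 > or1, I, 0.0)
    I = np.where(np.isfinite(I), I, 0.0)
    psi = rho * I.sum(axis=1)
    a, b, g = config.obc_alpha, config.obc_beta, config.obc_gamma
    inv = 1.0 / rho - np.tanh(a * psi - b * psi ** 2 + g * psi ** 3) / R
    if np.any(inv <= 0):
        bad = int(np.argmax(inv <= 0))
        raise EnergeticsError(f"nonpositive effective Born radius for atom {bad}")
    return 1.0 / inv


def gb_polar_energy(
    coords: np.ndarray,
    charge: np.ndarray,
    born_radius: np.ndarray,
    screen: np.ndarray,
    config: EnergeticsConfig | None = None,
    per_atom: bool = False,
):
    """Generalized-Born polar solvation energy (kcal/mol).

    E = -(k/2) sum_ij (1/eps_in - exp(-kappa f_ij)/eps_out) q_i q_j / f_ij
    with f_ij = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))) over all
    ordered pairs including self terms (f_ii = R_eff,i).
    """
    config = config or EnergeticsConfig()
    xyz = np.asarray(coords, dtype=float)
    q = np.asarray(charge, dtype=float)
    reff = effective_born_radii(xyz, born_radius, screen, config)
    r2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2)
    RR = np.outer(reff, reff)
    f = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
    D = 1.0 / config.eps_in - np.exp(-config.kappa * f) / config.eps_out
    E = -0.5 * config.coulomb_constant * D * np.outer(q, q) / f
    total = float(E.sum())
    if per_atom:
        return total, E.sum(axis=1)
    return total


def nonpolar_energy(
    s: MolecularStructure,
    config: EnergeticsConfig | None = None,
    mask: np.ndarray | None = None,
    coords: np.ndarray | None = None,
    per_atom: bool = False,
):
    """Surface-area nonpolar solvation term gamma * SASA + beta."""
    config = config or EnergeticsConfig()
    res = compute_sasa(
        s, probe=config.probe_radius, n_points=config.sasa_points,
        mask=mask, coords=coords,
    )
    total = config.gamma_np * res.total + config.beta_np
    if per_atom:
        shares = np.zeros(s.n_atoms)
        shares[res.atom_indices] = config.gamma_np * res.per_atom
        return total, shares
    return total


# ---------------------------------------------------------------------------
# Snapshot-ensemble binding energy
# ---------------------------------------------------------------------------

@dataclass
class BindingEnergyEstimate:
    """Snapshot-averaged binding energy with replica spread."""

    dg_bind: float
    sd: float                      # between-replica standard deviation
    components: dict[str, float]   # mean E_vdw, E_elec, dG_pol, dG_np
    per_replica: list[float]
    n_snapshots: int

    def summary(self) -> str:
        lines = [
            f"dG_bind = {self.dg_bind:.3f} +/- {self.sd:.3f} kcal/mol "
            f"({self.n_snapshots} snapshots, {len(self.per_replica)} replicas)",
        ]
        for k, v in self.components.items():
            lines.append(f"  {k:>8s} = {v:10.3f} kcal/mol")
        return "\n".join(lines)


def _binding_masks(
    s: MolecularStructure, a: ComplexAnnotation
) -> tuple[np.ndarray, np.ndarray]:
    base = s.heavy_mask()
    lig = base & s.chain_mask(a.tcr_chains())         # ligand: TCR
    rec = base & s.chain_mask(a.phla_chains())        # receptor: pHLA
    if not lig.any() or not rec.any():
        raise EnergeticsError("empty TCR or pHLA atom selection")
    return lig, rec


def _snapshot_terms(
    s: MolecularStructure,
    a: ComplexAnnotation,
    params: ForceFieldParameters,
    config: EnergeticsConfig,
    coords: np.ndarray,
    per_atom: bool = False,
):
    lig_mask, rec_mask = _binding_masks(s, a)
    both = np.flatnonzero(lig_mask | rec_mask)
    lig = np.flatnonzero(lig_mask)
    rec = np.flatnonzero(rec_mask)
    p = params.align(s, both)
    # positions of lig/rec atoms inside the `both` ordering
    pos = {g: i for i, g in enumerate(both)}
    la = np.array([pos[g] for g in lig], dtype=int)
    ra = np.array([pos[g] for g in rec], dtype=int)
    xyz = np.asarray(coords, dtype=float)[both]

    mm = mm_interaction_energy(
        xyz, p["charge"], p["rmin_half"], p["epsilon"], la, ra, config,
        per_atom=per_atom,
    )
    gb_c = gb_polar_energy(xyz, p["charge"], p["born_radius"], p["screen"],
                           config, per_atom=per_atom)
    gb_l = gb_polar_energy(xyz[la], p["charge"][la], p["born_radius"][la],
                           p["screen"][la], config, per_atom=per_atom)
    gb_r = gb_polar_energy(xyz[ra], p["charge"][ra], p["born_radius"][ra],
                           p["screen"][ra], config, per_atom=per_atom)
    np_c = nonpolar_energy(s, config, mask=(lig_mask | rec_mask), coords=coords,
                           per_atom=per_atom)
    np_l = nonpolar_energy(s, config, mask=lig_mask, coords=coords,
                           per_atom=per_atom)
    np_r = nonpolar_energy(s, config, mask=rec_mask, coords=coords,
                           per_atom=per_atom)
    if not per_atom:
        e_vdw, e_elec = mm
        dg_pol = gb_c - gb_l - gb_r
        dg_np = np_c - np_l - np_r
        return {"E_vdw": e_vdw, "E_elec": e_elec, "dG_pol": dg_pol,
                "dG_np": dg_np}

    e_vdw, e_elec, vdw_share, elec_share = mm
    gb_share = gb_c[1].copy()
    gb_share[la] -= gb_l[1]
    gb_share[ra] -= gb_r[1]
    np_share_c, np_share_l, np_share_r = np_c[1], np_l[1], np_r[1]
    np_share = np_share_c - np_share_l - np_share_r   # full-length arrays
    terms = {
        "E_vdw": e_vdw, "E_elec": e_elec,
        "dG_pol": gb_c[0] - gb_l[0] - gb_r[0],
        "dG_np": np_c[0] - np_l[0] - np_r[0],
    }
    shares = {
        "vdw": _expand(vdw_share, both, s.n_atoms),
        "elec": _expand(elec_share, both, s.n_atoms),
        "gb": _expand(gb_share, both, s.n_atoms),
        "np": np_share,
    }
    return terms, shares


def _expand(values: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(n)
    out[idx] = values
    return out


def _snapshot_list(ensemble_or_coords, config: EnergeticsConfig):
    """Normalize input to a list of per-replica coordinate lists."""
    from .ensemble import TrajectoryEnsemble

    if isinstance(ensemble_or_coords, TrajectoryEnsemble):
        reps = []
        for rep in range(ensemble_or_coords.n_replicas):
            frames = ensemble_or_coords.analyzed(rep)
            k = min(config.snapshot_count, len(frames))
            sel = np.linspace(0, len(frames) - 1, k).astype(int)
            reps.append([frames[i] for i in sel])
        return reps
    coords = list(ensemble_or_coords)
    if not coords:
        raise EnergeticsError("empty snapshot list")
    return [coords]


def mmgbsa_binding(
    snapshots,
    params: ForceFieldParameters,
    a: ComplexAnnotation,
    s: MolecularStructure,
    config: EnergeticsConfig | None = None,
) -> BindingEnergyEstimate:
    """Snapshot-averaged single-trajectory MM/GBSA binding energy.

    ``snapshots`` is a TrajectoryEnsemble (replicas respected; at most
    ``config.snapshot_count`` equally spaced frames per replica) or a
    plain list of coordinate arrays (treated as one replica).
    """
    config = config or EnergeticsConfig()
    reps = _snapshot_list(snapshots, config)
    per_replica, comp_acc, n_total = [], {}, 0
    for frames in reps:
        vals = []
        for xyz in frames:
            terms = _snapshot_terms(s, a, params, config, xyz)
            vals.append(sum(terms.values()))
            for k, v in terms.items():
                comp_acc[k] = comp_acc.get(k, 0.0) + v
            n_total += 1
        per_replica.append(float(np.mean(vals)))
    # snapshot-weighted grand mean (replicas normally share a frame count)
    dg = float(
        np.sum([m * len(f) for m, f in zip(per_replica, reps)])
        / sum(len(f) for f in reps)
    )
    sd = float(np.std(per_replica, ddof=1)) if len(per_replica) > 1 else 0.0
    return BindingEnergyEstimate(
        dg_bind=dg, sd=sd,
        components={k: v / n_total for k, v in comp_acc.items()},
        per_replica=per_replica, n_snapshots=n_total,
    )


# ---------------------------------------------------------------------------
# Per-residue decomposition and classification
# ---------------------------------------------------------------------------

@dataclass
class PerResidueEnergyTable:
    """Snapshot-averaged per-residue contributions to dG_bind."""

    table: pd.DataFrame   # chain, resnum, resname, role, vdw, elec, gb, np, total
    dg_bind: float
    label: str = ""

    def residue_total(self, chain: str, resnum: int) -> float:
        m = (self.table["chain"] == chain) & (self.table["resnum"] == resnum)
        return float(self.table.loc[m, "total"].sum())


def decompose_per_residue(
    snapshots,
    params: ForceFieldParameters,
    a: ComplexAnnotation,
    s: MolecularStructure,
    config: EnergeticsConfig | None = None,
    label: str = "",
) -> PerResidueEnergyTable:
    """Per-residue MM/GBSA decomposition; residue sums reproduce the total
    binding energy exactly (pairwise terms split half-half, self terms to
    the owning residue)."""
    config = config or EnergeticsConfig()
    reps = _snapshot_list(snapshots, config)
    frames = [xyz for rep in reps for xyz in rep]

    acc = {k: np.zeros(s.n_atoms) for k in ("vdw", "elec", "gb", "np")}
    dg_sum = 0.0
    for xyz in frames:
        terms, shares = _snapshot_terms(s, a, params, config, xyz, per_atom=True)
        dg_sum += sum(terms.values())
        for k in acc:
            acc[k] += shares[k]
    n = len(frames)
    dg_mean = dg_sum / n
    for k in acc:
        acc[k] /= n

    role_of = dict(a.role_map)
    rows: dict[tuple, dict] = {}
    for i in range(s.n_atoms):
        key = (str(s.chain_id[i]), int(s.resnum[i]))
        if key not in rows:
            rows[key] = {
                "chain": key[0], "resnum": key[1],
                "resname": str(s.resname[i]),
                "role": role_of.get(key[0], "other"),
                "vdw": 0.0, "elec": 0.0, "gb": 0.0, "np": 0.0,
            }
        for k in acc:
            rows[key][k] += float(acc[k][i])
    df = pd.DataFrame(list(rows.values()))
    df["total"] = df[["vdw", "elec", "gb", "np"]].sum(axis=1)
    return PerResidueEnergyTable(table=df, dg_bind=dg_mean, label=label)


@dataclass
class EnergyClassification:
    """Per-residue ddG (variant minus wild type) with the favorable /
    neutral / unfavorable labels at a +/- threshold band."""

    table: pd.DataFrame   # chain, resnum, resname_wt, resname_variant,
                          # ddg, label, mutated
    threshold: float


def classify_ddg(
    wt: PerResidueEnergyTable,
    variant: PerResidueEnergyTable,
    threshold: float = 0.5,
) -> EnergyClassification:
    """Classify per-residue ddG = dG_variant - dG_wt.

    favorable: ddG <= -threshold; unfavorable: ddG >= +threshold;
    neutral otherwise.  Positions whose residue identity changed are
    flagged as mutation sites.
    """
    wt_t = wt.table.set_index(["chain", "resnum"])
    var_t = variant.table.set_index(["chain", "resnum"])
    common = wt_t.index.intersection(var_t.index)
    rows = []
    for key in common:
        ddg = float(var_t.loc[key, "total"] - wt_t.loc[key, "total"])
        if ddg <= -threshold:
            label = "favorable"
        elif ddg >= threshold:
            label = "unfavorable"
        else:
            label = "neutral"
        rn_wt = str(wt_t.loc[key, "resname"])
        rn_var = str(var_t.loc[key, "resname"])
        rows.append({
            "chain": key[0], "resnum": key[1],
            "resname_wt": rn_wt, "resname_variant": rn_var,
            "ddg": ddg, "label": label, "mutated": rn_wt != rn_var,
        })
    return EnergyClassification(table=pd.DataFrame(rows), threshold=threshold)


# ---------------------------------------------------------------------------
# Experimental affinities
# ---------------------------------------------------------------------------

@dataclass
class AffinityRecord:
    """SPR-derived affinity for one complex (K_D in nM)."""

    label: str
    kd_nM: float
    on_rate: Optional[float] = None   # M^-1 s^-1
    off_rate: Optional[float] = None  # s^-1

    def __post_init__(self) -> None:
        if not self.kd_nM > 0:
            raise EnergeticsError(f"{self.label}: K_D must be positive")

    def kinetic_consistency(self, rtol: float = 0.5) -> Optional[bool]:
        """Check K_D ~ off/on when both rates are present (reported only)."""
        if not self.on_rate or not self.off_rate:
            return None
        kd_from_rates = self.off_rate / self.on_rate * 1e9
        return bool(abs(kd_from_rates - self.kd_nM) <= rtol * self.kd_nM)


def read_affinity_csv(path) -> list[AffinityRecord]:
    df = pd.read_csv(path)
    recs = []
    for r in df.itertuples(index=False):
        recs.append(AffinityRecord(
            label=str(r.label), kd_nM=float(r.kd_nM),
            on_rate=float(r.on_rate) if pd.notna(getattr(r, "on_rate", np.nan)) else None,
            off_rate=float(r.off_rate) if pd.notna(getattr(r, "off_rate", np.nan)) else None,
        ))
    return recs


def kd_to_dg(rec: AffinityRecord, config: EnergeticsConfig | None = None) -> float:
    """Standard-state binding free energy dG = RT ln(K_D in M), kcal/mol."""
    config = config or EnergeticsConfig()
    return config.rt * float(np.log(rec.kd_nM * 1e-9))


def fold_change(wt: AffinityRecord, variant: AffinityRecord) -> float:
    """Affinity gain K_D(wt) / K_D(variant)."""
    return wt.kd_nM / variant.kd_nM


def ddg_exp(
    wt: AffinityRecord,
    variant: AffinityRecord,
    config: EnergeticsConfig | None = None,
) -> float:
    """Experimental ddG = RT ln(K_D,variant / K_D,wt), kcal/mol."""
    config = config or EnergeticsConfig()
    return config.rt * float(np.log(variant.kd_nM / wt.kd_nM))


def rank_correlation(
    computed: Sequence[float], experimental: Sequence[float]
) -> dict:
    """Sign agreement and Spearman rank correlation of two ddG lists."""
    x = np.asarray(computed, dtype=float)
    y = np.asarray(experimental, dtype=float)
    if len(x) != len(y):
        raise EnergeticsError("computed and experimental lists differ in length")
    if len(x) < 2:
        raise EnergeticsError("need at least two pairs")
    signs = np.sign(x) == np.sign(y)
    rho, pval = stats.spearmanr(x, y)
    return {
        "n": int(len(x)),
        "sign_agreement": float(signs.mean()),
        "n_sign_agree": int(signs.sum()),
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
    }
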