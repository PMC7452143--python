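"""Replica-ensemble statistics: RMSF, flexibility comparison, averaged
contacts, hydrogen-bond occupancy and frame-averaged interface burial.

An ensemble is a list of replicas, each a (frames, atoms, 3) coordinate
array tied to one topology structure.  Per-residue flexibility is
compared between two ensembles with a two-sample t test on the
per-replica RMSF values (replicas, not frames, are the independent
units), Welch-corrected by default and without multiple-testing
correction.  The first ``burn_in_fraction`` of each replica is discarded
from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactCriteria, find_contacts, per_residue_contact_map
from .structure import ComplexAnnotation, MolecularStructure
from .surface import compute_bsasa

__all__ = [
    "TrajectoryEnsemble",
    "FlexibilityComparison",
    "OccupancySeries",
    "align_frames",
    "compute_rmsf",
    "compare_rmsf",
    "average_contacts",
    "hb_occupancy",
    "average_bsasa",
]


class EnsembleError(ValueError):
    pass


@dataclass
class TrajectoryEnsemble:
    """Replicas x frames of coordinates tied to one topology."""

    topology: MolecularStructure
    replicas: list[np.ndarray]            # each (frames, n_atoms, 3)
    frame_interval_ns: float = 0.1
    burn_in_fraction: float = 0.10
    aligned: bool = False

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        self.replicas = [np.asarray(r, dtype=float) for r in self.replicas]
        for i, r in enumerate(self.replicas):
            if r.ndim != 3 or r.shape[1] != n or r.shape[2] != 3:
                raise EnsembleError(
                    f"replica {i} shape {r.shape} inconsistent with "
                    f"{n}-atom topology"
                )
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise EnsembleError("burn_in_fraction must be in [0, 1)")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def analyzed(self, replica: int) -> np.ndarray:
        """Frames of one replica after burn-in removal."""
        r = self.replicas[replica]
        start = int(np.ceil(self.burn_in_fraction * len(r)))
        out = r[start:]
        if len(out) == 0:
            raise EnsembleError(f"replica {replica} has no frames after burn-in")
        return out

    # -- I/O ---------------------------------------------------------------

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            **{f"replica_{i}": r for i, r in enumerate(self.replicas)},
            frame_interval_ns=self.frame_interval_ns,
            burn_in_fraction=self.burn_in_fraction,
        )

    @classmethod
    def from_npz(cls, topology: MolecularStructure, path) -> "TrajectoryEnsemble":
        data = np.load(path)
        keys = sorted(
            (k for k in data.files if k.startswith("replica_")),
            key=lambda k: int(k.split("_")[1]),
        )
        return cls(
            topology=topology,
            replicas=[data[k] for k in keys],
            frame_interval_ns=float(data.get("frame_interval_ns", 0.1)),
            burn_in_fraction=float(data.get("burn_in_fraction", 0.10)),
        )

    @classmethod
    def from_multi_model_pdbs(
        cls,
        topology: MolecularStructure,
        paths: Sequence,
        **kwargs,
    ) -> "TrajectoryEnsemble":
        """One multi-model PDB file per replica; atom order must match the
        topology."""
        import gemmi

        replicas = []
        for p in paths:
            st = gemmi.read_pdb(str(Path(p)))
            frames = []
            for model in st:
                xyz = [
                    (at.pos.x, at.pos.y, at.pos.z)
                    for ch in model for res in ch for at in res
                ]
                frames.append(xyz)
            arr = np.asarray(frames, dtype=float)
            if arr.shape[1] != topology.n_atoms:
                raise EnsembleError(
                    f"{p}: {arr.shape[1]} atoms per model, topology has "
                    f"{topology.n_atoms}"
                )
            replicas.append(arr)
        return cls(topology=topology, replicas=replicas, **kwargs)


def _selection_indices(
    e: TrajectoryEnsemble, selection: Optional[Sequence[tuple[str, int]]]
) -> np.ndarray:
    top = e.topology
    ca = (top.name == "CA") & ~top.is_hydrogen & ~top.is_water
    if selection is None:
        idx = np.flatnonzero(ca)
    else:
        keys = set(selection)
        idx = np.flatnonzero(ca)
        idx = np.array(
            [i for i in idx if (str(top.chain_id[i]), int(top.resnum[i])) in keys],
            dtype=int,
        )
    if len(idx) == 0:
        raise EnsembleError("empty alignment selection")
    return idx


def align_frames(
    e: TrajectoryEnsemble,
    selection: Optional[Sequence[tuple[str, int]]] = None,
    tol: float = 1e-10,
    max_iter: int = 20,
) -> TrajectoryEnsemble:
    """Least-squares superpose every frame onto the ensemble-average
    reference, refined iteratively to self-consistency, using C-alpha
    atoms of ``selection`` (all residues when None).

    At convergence the frames are optimally aligned to their own mean, so
    a second call is a no-op.
    """
    from .geometry import kabsch

    idx = _selection_indices(e, selection)
    replicas = [r.copy() for r in e.replicas]

    def fit_all(reference_sel: np.ndarray) -> None:
        for r in replicas:
            for f in range(len(r)):
                R, t = kabsch(r[f, idx], reference_sel)
                r[f] = r[f] @ R.T + t

    ref = np.mean([r[:, idx].mean(axis=0) for r in replicas], axis=0)
    for _ in range(max_iter):
        fit_all(ref)
        new_ref = np.mean([r[:, idx].mean(axis=0) for r in replicas], axis=0)
        shift = float(np.abs(new_ref - ref).max())
        ref = new_ref
        if shift < tol:
            break
    return replace(e, replicas=replicas, aligned=True)


def compute_rmsf(e: TrajectoryEnsemble) -> pd.DataFrame:
    """Per-residue, per-replica C-alpha RMSF (A) after burn-in removal.

    RMSF_i = sqrt(<|r_i - <r_i>|^2>) over the analyzed frames of one
    replica.
    """
    top = e.topology
    ca_idx = np.flatnonzero((top.name == "CA") & ~top.is_hydrogen & ~top.is_water)
    if len(ca_idx) == 0:
        raise EnsembleError("topology has no C-alpha atoms")
    rows = []
    for rep in range(e.n_replicas):
        frames = e.analyzed(rep)[:, ca_idx]
        if len(frames) < 2:
            raise EnsembleError(
                f"replica {rep} has {len(frames)} analyzed frames; need >= 2"
            )
        mean = frames.mean(axis=0)
        msd = ((frames - mean) ** 2).sum(axis=2).mean(axis=0)
        rmsf = np.sqrt(msd)
        for i, atom in enumerate(ca_idx):
            rows.append({
                "chain": str(top.chain_id[atom]),
                "resnum": int(top.resnum[atom]),
                "replica": rep,
                "rmsf": float(rmsf[i]),
            })
    return pd.DataFrame(rows)


@dataclass
class FlexibilityComparison:
    """Per-residue RMSF comparison between two ensembles."""

    table: pd.DataFrame          # chain, resnum, rmsf_wt, rmsf_variant,
                                 # delta_rmsf, p_value, significant
    alpha: float
    welch: bool
    dropped_wt: list = field(default_factory=list)
    dropped_variant: list = field(default_factory=list)

    @property
    def significant_residues(self) -> list[tuple[str, int]]:
        sig = self.table[self.table["significant"]]
        return list(zip(sig["chain"], sig["resnum"]))


def compare_rmsf(
    wt: TrajectoryEnsemble,
    variant: TrajectoryEnsemble,
    alpha: float = 0.05,
    welch: bool = True,
    selection: Optional[Sequence[tuple[str, int]]] = None,
    align: bool = True,
) -> FlexibilityComparison:
    """Two-sample t test on per-replica RMSF values, residue by residue.

    The sample unit is the replica (n = replica count per side); no
    multiple-testing correction is applied.  Residues without a partner
    on the other side are dropped and reported.
    """
    for name, e in (("wt", wt), ("variant", variant)):
        if e.n_replicas < 2:
            raise EnsembleError(
                f"{name} ensemble has {e.n_replicas} replicas; "
                "significance testing needs >= 2"
            )
    if align:
        wt = wt if wt.aligned else align_frames(wt, selection)
        variant = variant if variant.aligned else align_frames(variant, selection)
    r_wt = compute_rmsf(wt).pivot_table(
        index=["chain", "resnum"], columns="replica", values="rmsf"
    )
    r_var = compute_rmsf(variant).pivot_table(
        index=["chain", "resnum"], columns="replica", values="rmsf"
    )
    common = r_wt.index.intersection(r_var.index)
    dropped_wt = [t for t in r_wt.index if t not in common]
    dropped_var = [t for t in r_var.index if t not in common]

    rows = []
    for key in common:
        x = r_wt.loc[key].to_numpy()
        y = r_var.loc[key].to_numpy()
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # degenerate: no variance on either side
            p = 1.0 if x.mean() == y.mean() else 0.0
        else:
            p = float(stats.ttest_ind(x, y, equal_var=not welch).pvalue)
        rows.append({
            "chain": key[0], "resnum": key[1],
            "rmsf_wt": float(x.mean()), "rmsf_variant": float(y.mean()),
            "delta_rmsf": float(y.mean() - x.mean()),
            "p_value": p, "significant": bool(p < alpha),
        })
    return FlexibilityComparison(
        table=pd.DataFrame(rows), alpha=alpha, welch=welch,
        dropped_wt=dropped_wt, dropped_variant=dropped_var,
    )


def average_contacts(
    e: TrajectoryEnsemble,
    a: ComplexAnnotation,
    criteria: ContactCriteria | None = None,
) -> pd.DataFrame:
    """Mean per-pHLA-residue contact counts over frames, replica-averaged.

    Counts are averaged within each replica first, then across replicas
    with equal weight (replicas may differ in frame count).
    """
    criteria = criteria or ContactCriteria()
    per_rep: list[pd.DataFrame] = []
    for rep in range(e.n_replicas):
        frames = e.analyzed(rep)
        acc: dict[tuple, np.ndarray] = {}
        for f in range(len(frames)):
            table = find_contacts(e.topology, a, criteria, coords=frames[f])
            cmap = per_residue_contact_map(table)
            for _, row in cmap.iterrows():
                key = (row["target"], row["target_chain"], int(row["target_resnum"]))
                acc[key] = acc.get(key, np.zeros(2)) + [row["n_vdw"], row["n_hb"]]
        rows = [
            {"target": k[0], "target_chain": k[1], "target_resnum": k[2],
             "mean_vdw": v[0] / len(frames), "mean_hb": v[1] / len(frames)}
            for k, v in acc.items()
        ]
        per_rep.append(pd.DataFrame(
            rows, columns=["target", "target_chain", "target_resnum",
                           "mean_vdw", "mean_hb"]))
    merged = pd.concat(per_rep, ignore_index=True)
    if merged.empty:
        return merged
    out = merged.groupby(
        ["target", "target_chain", "target_resnum"], sort=True
    ).agg(mean_vdw=("mean_vdw", "sum"), mean_hb=("mean_hb", "sum")).reset_index()
    out[["mean_vdw", "mean_hb"]] /= e.n_replicas
    return out


@dataclass
class OccupancySeries:
    """Hydrogen-bond occupancy per candidate pair."""

    table: pd.DataFrame    # donor, acceptor, replica, occupancy
    cutoff: float

    def pooled(self) -> pd.DataFrame:
        return (
            self.table.groupby(["donor", "acceptor"])["occupancy"]
            .mean().reset_index(name="occupancy")
        )


def hb_occupancy(
    e: TrajectoryEnsemble,
    pairs: Sequence[tuple[tuple[str, int, str], tuple[str, int, str]]],
    cutoff: float = 3.4,
) -> OccupancySeries:
    """Fraction of analyzed frames with donor-acceptor distance <= cutoff.

    ``pairs`` are ((chain, resnum, atom), (chain, resnum, atom)) tuples;
    unknown atoms raise KeyError.
    """
    top = e.topology
    idx_pairs = [
        (top.atom_index(*d), top.atom_index(*acc)) for d, acc in pairs
    ]
    rows = []
    for rep in range(e.n_replicas):
        frames = e.analyzed(rep)
        for (di, ai), (dspec, aspec) in zip(idx_pairs, pairs):
            d = np.linalg.norm(frames[:, di] - frames[:, ai], axis=1)
            rows.append({
                "donor": "/".join(map(str, dspec)),
                "acceptor": "/".join(map(str, aspec)),
                "replica": rep,
                "occupancy": float((d <= cutoff).mean()),
            })
    return OccupancySeries(table=pd.DataFrame(rows), cutoff=cutoff)


def average_bsasa(
    e: TrajectoryEnsemble,
    a: ComplexAnnotation,
    probe: float = 1.4,
    n_points: int = 240,
    max_frames_per_replica: Optional[int] = None,
) -> dict:
    """Frame-averaged interface burial: per-replica means, grand mean and
    between-replica standard deviation."""
    per_replica = []
    for rep in range(e.n_replicas):
        frames = e.analyzed(rep)
        if max_frames_per_replica and len(frames) > max_frames_per_replica:
            sel = np.linspace(0, len(frames) - 1, max_frames_per_replica).astype(int)
            frames = frames[sel]
        vals = [
            compute_bsasa(e.topology, a, probe=probe, n_points=n_points,
                          coords=frames[f])
            for f in range(len(frames))
        ]
        per_replica.append(float(np.mean(vals)))
    grand = float(np.mean(per_replica))
    sd = float(np.std(per_replica, ddof=1)) if len(per_replica) > 1 else 0.0
    return {"per_replica_mean": per_replica, "mean": grand, "sd": sd}
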