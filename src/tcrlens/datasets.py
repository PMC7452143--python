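"""Bundled input tables.

``affinities.csv`` holds published SPR affinities (K_D in nM, on-rate in
1/(M s), off-rate in 1/s) for the wild-type / affinity-enhanced TCR pairs
studied against HLA-A*02:01-presented peptides, keyed by a short label
and the PDB accession of each complex.  These are experimental inputs,
used to compute binding free energies and fold changes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .energetics import AffinityRecord

__all__ = ["load_affinity_table", "affinity_record", "WT_VARIANT_PAIRS"]

#: wild-type / variant label pairs sharing a peptide-HLA system
WT_VARIANT_PAIRS = [
    ("1G4_wt", "1G4_c5c1"),
    ("1G4_wt", "1G4_c49c50"),
    ("1G4_wt", "1G4_c58c61"),
    ("DMF5_wt", "DMF5_YW"),
    ("MEL5_wt_ELA", "MEL5_a24b17_ELA"),
    ("MEL5_wt_EAA", "MEL5_a24b17_EAA"),
    ("MEL5_wt_AAG", "MEL5_a24b17_AAG"),
    ("A6_wt", "A6_c134"),
    ("ILA1_wt", "ILA1_a1b1"),
]


def load_affinity_table() -> pd.DataFrame:
    with resources.files("tcrlens.data").joinpath("affinities.csv").open() as fh:
        return pd.read_csv(fh)


def affinity_record(label: str) -> AffinityRecord:
    df = load_affinity_table()
    row = df[df["label"] == label]
    if row.empty:
        raise KeyError(f"no affinity record labelled {label!r}")
    r = row.iloc[0]
    return AffinityRecord(
        label=label,
        kd_nM=float(r["kd_nM"]),
        on_rate=float(r["on_rate"]) if pd.notna(r["on_rate"]) else None,
        off_rate=float(r["off_rate"]) if pd.notna(r["off_rate"]) else None,
    )
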