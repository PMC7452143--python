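# tcrlens

Structural and energetic comparison of wild-type and affinity-enhanced
T cell receptor (TCR) complexes with peptide-HLA (pHLA).

Natural TCRs bind cancer-derived pHLA with weak, micromolar affinities.
Engineered, affinity-enhanced TCRs (aeTCRs) reach nanomolar-to-picomolar
affinities — up to ~300,000-fold gains — while, remarkably, preserving
the native diagonal docking mode. `tcrlens` packages the analyses used
to characterise *how* such enhancement works at the interface:

- **Binding geometry** — the crossing angle between the Vα→Vβ
  interdomain vector and the peptide-groove axis, and the docking
  footprint of the combined variable-domain centroid over the groove.
- **Interface contacts** — van der Waals (≤ 4.0 Å), hydrogen-bond
  (≤ 3.4 Å, donor/acceptor typed) and salt-bridge (≤ 3.4 Å, charged
  side-chain pairs) contacts between TCR and peptide/HLA, with
  wild-type/variant Δ-count and top-contact-preservation reports.
- **Surface burial and fit** — Shrake–Rupley solvent-accessible surface
  area, buried SASA of the interface
  (BSASA = SASA(TCR) + SASA(pHLA) − SASA(complex)), and the
  Lawrence–Colman shape-complementarity statistic S_C.
- **Ensemble flexibility** — per-residue Cα RMSF over replica
  ensembles, ΔRMSF between wild type and variant with per-residue
  two-sample t tests (the replica is the sampling unit), hydrogen-bond
  occupancies and frame-averaged contacts/BSASA.
- **Energetics** — a simplified single-trajectory MM/GBSA estimator,

      ΔG_bind = E_vdW + E_elec + ΔG_polar(GB, OBC-II) + γ·ΔSASA,

  with exact per-residue decomposition (residue contributions sum to the
  total), ΔΔG = ΔG_variant − ΔG_wt classification at a ±0.5 kcal/mol
  band, and experimental ΔG = RT ln K_D conversions from SPR affinities.
- **Synthetic fixtures** — seeded toy complexes with exact planted
  crossing angles, footprints and contacts, and replica ensembles with
  planted per-residue fluctuation profiles, so every metric can be
  validated against its construction value.

## Worked example

```sh
# build a toy complex with a known geometry and two planted hydrogen bonds
tcrlens simulate complex --seed 3 --angle 52.5 --hb-contacts 2 --out toy/

tcrlens geometry toy/complex.pdb --config toy/annotation.yaml
```

prints

```json
{
  "entry_id": "complex",
  "crossing_angle_deg": 52.500403011027814,
  "definition_tag": "disulfide_ca",
  "footprint_x_A": -4.444444442109033e-06,
  "footprint_y_A": -1.3333333334360178e-05
}
```

i.e. the toy TCR docks at the requested 52.5° over the groove centre
(footprint ≈ (0, 0) Å). Contacts and experimental energetics:

```sh
tcrlens contacts toy/complex.pdb --config toy/annotation.yaml --out toy/contacts.csv
# -> "2 contacts -> toy/contacts.csv"   (the two planted hydrogen bonds)

python - <<'PY'
from tcrlens.datasets import affinity_record
from tcrlens.energetics import fold_change, ddg_exp
wt, var = affinity_record("MEL5_wt_ELA"), affinity_record("MEL5_a24b17_ELA")
print(f"fold = {fold_change(wt, var):.0f}, ddG_exp = {ddg_exp(wt, var):.2f} kcal/mol")
PY
# -> fold = 29508, ddG_exp = -6.10 kcal/mol
```

The MEL5 variant binds ~30,000-fold tighter than its wild-type
progenitor, a ΔΔG of −6.1 kcal/mol at 298.15 K.

The `tcrlens compare` command runs the whole geometry / contacts /
surface pipeline over a manifest of wild-type/variant pairs and writes
summary and comparison CSVs mirroring the per-complex and per-pair
metrics above.

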