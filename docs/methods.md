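# Methods

This note documents the models and procedures implemented in `tcrlens`,
the defaults and why they were chosen, what the synthetic fixtures do
and do not emulate, and the numerical choices that affect results.

## Structures and annotation

Structures are parsed from standard PDB files (gemmi backend) into a
flat per-atom table keyed by (chain, author residue number, insertion
code, atom name). Alternate locations are resolved by keeping the
highest-occupancy conformer (ties: first altloc in file order), because
all static comparisons here are single-conformer analyses; `first` and
`all` policies are available. Hydrogens and waters are retained in the
model but excluded from every default analysis selection; waters never
participate in interface metrics.

Chain roles (TCR α/β, HLA heavy chain, β2-microglobulin, peptide) come
from an explicit YAML config whenever supplied. Without one, a length
heuristic applies: peptide 8–13 aa, β2m 95–105 aa, HLA heavy 260–290 aa,
and the remaining two 170–260 aa chains become TCRα/TCRβ in declared
file order. Any ambiguity is an error listing the candidates. Loop
(CDR1-3, HV4) and variable-domain ranges are **never** guessed: they are
taken from the config, in author numbering, because deposited TCR
structures use heterogeneous numbering schemes. A documented IMGT
template ships in `src/tcrlens/data/loop_ranges_imgt.yaml` as a starting
point; mutation labels in the literature (e.g. D26Y, L98W) are author
numbering, so per-entry curation is unavoidable.

Sequence differences between wild-type and variant complexes use global
pairwise alignment (Biopython `PairwiseAligner`; match 2, mismatch −1,
gap open −5, extend −0.5). Substitutions are reported in wild-type
author numbering with their loop label; insertions/deletions are listed
separately and never counted as substitutions. Alignment identity below
70% (configurable) is treated as chain mispairing and raised as an
error.

## Binding geometry

All docking metrics are expressed in a groove frame: origin at the
peptide Cα centroid; x the first principal component of the peptide Cα
trace, oriented N→C; y the α1-minus-α2 helix-centroid direction
orthogonalised against x (α1 side positive); z = x × y pointing from the
groove toward the TCR.

The **crossing angle** is the unsigned angle in [0°, 180°) between the
Vα-centroid→Vβ-centroid vector projected into the groove plane and the
peptide axis. Two centroid rules are provided and always recorded in the
output: `disulfide_ca` (centroid of the two conserved intradomain
cysteine Cα per variable domain; the default, matching common practice)
and `domain_ca` (all variable-domain Cα). No single published formula
exists for this quantity; the two rules agree within a few degrees on
well-formed complexes and the definition tag keeps results comparable.
The **footprint** is the (x, y) displacement of the combined Vα+Vβ Cα
centroid from the groove origin; Cα-only centroids are robust to
side-chain disorder and differ negligibly from heavy-atom centroids.

Loop displacement between two complexes superposes the variant onto the
wild type on matched HLA-heavy-chain Cα atoms (least squares, Kabsch)
and reports per-loop backbone (N, Cα, C, O) RMSD over alignment-matched
positions; atoms missing on either side are skipped and counted, and a
loop with no matched positions is flagged not comparable rather than
failing the run.

## Contacts

A contact is a heavy-atom pair (one TCR atom, one peptide or HLA-heavy
atom) within 4.0 Å. Hydrogen bonds are distance-only (≤ 3.4 Å) with
donor/acceptor typing derived from residue chemistry (backbone N donates
except proline; backbone O/OXT accepts; standard side-chain
donor/acceptor sets); no angular criterion is applied by default because
the distance definition is the published convention here — an optional
D–H···A ≥ 120° filter exists for structures with hydrogens. Salt
bridges pair Lys NZ / Arg NE,NH1,NH2 (His ND1/NE2 only when flagged
protonated; His is neutral by default) with Asp OD1,OD2 / Glu OE1,OE2 at
≤ 3.4 Å. Types are *tags on one row*, not exclusive bins: vdW counts
include pairs that are also HB/SB, since typed counts are reported
independently.

Wild-type/variant comparison reports Δcounts per type and per target
(peptide / HLA / total) and a preservation score: of the wild type's
k = 10 most-contacted pHLA residues (ranked by total contact rows, ties
by residue order), how many still make ≥ 1 contact (configurable) in the
variant. The search uses a k-d tree; an O(N²) enumeration oracle in the
test suite guarantees the acceleration changes nothing.

## Surface area and shape complementarity

SASA uses Shrake–Rupley quadrature with a deterministic golden-spiral
point set (default 960 points, probe 1.4 Å, Bondi-style element radii
documented in `tcrlens.surface.BONDI_RADII`). The isolated-sphere error
at 960 points is far below 1%, and doubling the point count moves
totals by < 0.5% on cluster fixtures. Component SASAs are computed by
restricting the atom set (nothing is moved), so

    BSASA = SASA(TCR) + SASA(pHLA) − SASA(complex)

is reported as total burial (a `half` flag gives the per-side
convention). The pHLA entity comprises heavy chain, β2m and peptide.

Shape complementarity implements the Lawrence–Colman statistic on dot
surfaces: exposed points on each side's van der Waals surface (probe
inflation optional), each scored against the nearest point of the other
surface within a 1.5 Å band as (n_a · −n_b) exp(−w d²) with w = 0.5 Å⁻²;
S_C is the mean of the two per-side medians. Published S_C values for
these complexes were produced by interface servers whose algorithms are
not bit-reproducible; this implementation claims ranking agreement, not
numeric equality, with such values. Because the quadrature directions
are lab-fixed, rigid-body invariance holds only to dot-surface
resolution (a few hundredths of S_C at default settings).

## Replica-ensemble statistics

An ensemble is a list of replicas, each (frames × atoms × 3), tied to
one topology; readers exist for multi-model PDB (one file per replica)
and a compressed NPZ container. The first 10% of each replica is
discarded (burn-in, configurable), mirroring the convention of analysing
the tail of each production run. Frames are superposed on selection Cα
atoms onto the ensemble-mean reference, iterated to self-consistency so
that alignment is idempotent; the default selection is all Cα, and a
framework-only selection can be passed where loops would bias the fit.

RMSF is per replica: RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩) over analysed
frames. ΔRMSF significance uses a per-residue two-sample t test on the
**per-replica** RMSF values — replicas, not frames, are the independent
units — Welch-corrected by default (a pooled-variance flag exists), at
α = 0.05 with no multiple-testing correction, since the flag is a
per-residue descriptive device, not a family-wise claim. With ~100
monitored residues this implies ~5 expected false flags per comparison;
the acceptance suite checks exactly this calibration (type-I ≈ α on
null ensembles) together with full power on planted σ-doublings.
Degenerate residues (zero variance on both sides, equal means) are
reported as not significant.

Hydrogen-bond occupancy is the fraction of analysed frames with
donor–acceptor heavy-atom distance ≤ 3.4 Å, per replica and pooled.
Frame-averaged contact maps average within replica first, then across
replicas with equal weight; frame-averaged BSASA reports per-replica
means, the grand mean and the between-replica SD.

## Energetics

The binding-energy estimator is a deliberately simplified,
single-trajectory MM/GBSA in kcal/mol (Å, e):

- **Molecular mechanics**: gas-phase pairwise sums with no cutoff
  between the TCR (ligand) and pHLA (receptor) atom sets. Coulomb
  k q_i q_j / (ε_in r) with k = 332.0637 kcal·Å/(mol·e²), ε_in = 1
  (the interior dielectric is configurable); Lennard-Jones from
  rmin_ij = rmin_half_i + rmin_half_j and ε_ij = sqrt(ε_i ε_j). In the
  single-trajectory convention receptor/ligand conformations are
  extracted from complex frames, so internal MM terms cancel exactly
  and only the interaction terms remain.
- **Polar solvation**: generalized Born with OBC-II rescaled
  Hawkins–Cramer–Truhlar pairwise descreening (offset 0.09 Å; tanh
  coefficients 1.0, 0.8, 4.85) and Debye–Hückel salt screening via
  exp(−κ f_ij)/ε_out with κ = 50.29216 · sqrt(I / (ε_out T)) Å⁻¹,
  I = 0.150 M and ε_out = 78.5 by default. The GB flavour used to
  produce the published numbers relies on implementation-specific neck
  integral tables; OBC-II is used here because the estimator's contract
  is relative ranking of similar complexes, not absolute energies —
  MM/GBSA should not be read as absolute affinity in any flavour.
- **Nonpolar solvation**: γ·SASA + β with γ = 0.0072 kcal/(mol·Å²),
  β = 0.
- **Entropy**: omitted (no normal-mode term), consistent with a
  ranking-only contract.

Per-atom parameters (charge, rmin/2, ε, intrinsic Born radius,
screening factor) are *inputs*, read from a documented
whitespace-delimited table; deriving force-field parameters is out of
scope, and a seeded toy parameter generator serves the tests.

Snapshot ensembles average ΔG over up to 300 equally spaced frames per
replica (configurable) and report the between-replica SD. Per-residue
decomposition splits every pairwise term half-and-half between the two
partner residues and assigns self terms to the owner, for all four
components (the symmetric split is a documented choice among several
defensible attributions); residue contributions therefore sum to the
total ΔG exactly (bookkeeping identity, tested to 1e-6; with a nonzero
β the constant offset belongs to the total only). ΔΔG per residue
(variant − wild type, matched by chain and residue number, mutated
positions flagged) is classified favorable (≤ −0.5), neutral, or
unfavorable (≥ +0.5 kcal/mol); the threshold is configurable and the
three-band reading resolves an ambiguity in how such maps are usually
captioned.

Experimental conversions: ΔG = RT ln K_D (K_D in M) at T = 298.15 K
(R = 1.9872×10⁻³ kcal/(mol·K)); ΔΔG_exp = RT ln(K_D,variant/K_D,wt);
fold change K_D,wt/K_D,variant. When both kinetic rates accompany a
K_D, their consistency (K_D ≈ k_off/k_on) is checked and reported, never
enforced. Computed-vs-experimental ΔΔG lists are compared by per-pair
sign agreement and Spearman rank correlation.

## Synthetic fixtures

The toy complex is a Cα-plus-probe-atom construction, not a physically
realistic protein: a peptide trace (3.8 Å spacing) along x, two helix
traces at y = ±9 Å, filler slabs below for the HLA body and β2m, and
two variable-domain point clouds (mean-centred, so domain centroids are
exact) placed 20 Å apart at 25 Å above the groove so that the requested
crossing angle and footprint hold *by construction*. Planted contacts
add single probe atoms (backbone-N/O pairs for HBs, apolar carbons for
vdW, Lys-NZ/Glu-OE1 for salt bridges) at exact distances, isolated from
all other atoms. Chain lengths (276/99/9/200/240 aa) exercise the
role-assignment heuristic. Ensembles add i.i.d. isotropic Gaussian
jitter with a per-residue σ profile (so RMSF = σ√3) and optional
two-state hydrogen-bond switching with planted occupancy.

What this validates: the geometry operators, contact typing and
enumeration, the statistical calibration of the flexibility comparison,
occupancy estimation, and all energy bookkeeping — each against planted
ground truth or closed forms. What it does not emulate: real side-chain
packing, correlated (non-i.i.d.) backbone dynamics, solvent structure,
or force-field realism; passing these tests therefore certifies the
*machinery*, while conclusions about real complexes still inherit the
approximations of the structures, parameters and sampling supplied by
the user. All generator randomness flows through one
`numpy.random.default_rng(seed)`; generation is bit-reproducible.

## Problem sizes in the acceptance run

`scripts/acceptance.py` uses fixture sizes chosen to make the
statistical assertions sharp on a single CPU in minutes: RMSF recovery
on 200 residues × 10 replicas × 1000 frames; planted-detection over 20
generator seeds at 10 × 500 frames (120 residues, σ 0.3→0.6 Å on
residues 95–100); the null calibration over 200 repetitions (30
residues, 10 × 50 frames); 100 random interfaces for the contact
oracle; 50 random specs for the geometry round trip. The experimental
fold-change and ΔΔG values are exact arithmetic on the bundled affinity
table and independent of the seed.

## Known limitations

- Crossing-angle conventions differ across the literature by the choice
  of centroid and reference axis; values carry a definition tag and
  cross-definition comparisons should expect a few degrees of spread.
- S_C here is not numerically interchangeable with interface-server
  output (see above).
- The GB model is OBC-II, not a neck-corrected variant; salt enters
  only through Debye screening of the pairwise GB term.
- HB detection is distance-only by default; no water-mediated bonds,
  π-stacking or cation-π interactions are detected.
- The t-test flags are per-residue and uncorrected by design; treat the
  flagged set as descriptive, not as a family-wise inference.
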