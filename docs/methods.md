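# Methods

This note documents the models, conventions and parameter choices behind
`cpfatools`, and what the synthetic-data results do and do not show about
real data.

## Lipid library

Positions index the backbone from the carboxyl carbon C1, so a
modification at `p` spans carbons `p` and `p+1` (`C18:1 cis-9` is oleic
acid; the CpFA ring methylene is not counted in `p` or in the backbone
length). Enumerating one SFA per length and positions `p = 2..n−1` for
MUFA/CpFA over lengths 12–24 gives 13 + 208 + 208 = 429 species. SMILES
are isomer-explicit: MUFAs carry Z double-bond direction marks; CpFA ring
stereochemistry is encoded with like tetrahedral marks on the two ring
base carbons (`[C@H]1C[C@H]1`), which places both chain substituents on
the same ring face (verified by 3D embedding during development). Species
whose modification sits at the chain terminus (`p = n−1`) have no
cis/trans isomerism and are emitted without stereo marks.

## Conformer engine

Geometries come from fixed internal-coordinate templates via the
natural-extension reference frame construction:

| element | bond | angle | dihedral |
|---|---|---|---|
| sp³ C–C | 1.53 Å | 111° | rotatable |
| cis C=C | 1.33 Å | 120° | fixed 0° |
| cyclopropane ring C–C | 1.51 Å | ≈117.7° backbone angle | fixed 0° (eclipsed) |

The cyclopropane is an equilateral triangle; its exocyclic substituent
directions follow from a 115° exocyclic angle split symmetrically about
the ring plane, which makes the two chain substituents *cis* and exactly
eclipses the backbone across the ring bond — the geometric origin of the
MUFA-like bend. Carboxyl oxygens sit in the C1 sp² plane at 1.25 Å / 120°.
Hydrogens are not modeled; every descriptor uses carbon coordinates only.

Sampling draws each rotatable torsion from the staggered rotamers
(anti 180°, gauche ±65°) with Boltzmann-style weights (0.69 / 0.155 /
0.155, i.e. a ~0.9 kcal/mol gauche penalty at 298 K) plus 10° Gaussian
jitter. Candidates are rejected by a hard-sphere clash filter (no carbon
pair ≥ 4 bonds apart closer than 2.8 Å), ranked by total rotamer strain
(0.9 kcal/mol per gauche), and accepted lowest-strain-first subject to a
0.5 Å backbone-RMSD redundancy filter (Kabsch superposition). This
emulates a low-energy-first commercial conformer generator without a
force field: it preserves the *shape statistics* (extended-chain-dominated
ensembles, persistent cis kinks) but not any particular tool's conformer
sets or energies. Each lipid draws from its own seeded stream (seed ⊕
CRC32 of the lipid name), so library runs are order-independent. Short
chains have few distinct rotamer states and may produce fewer conformers
than requested; this is reported, not fatal.

## Shape descriptors

`d_ee` uses the backbone termini C1 and Cn; the CpFA ring methylene is a
side branch and is excluded there, but is included in `R_g` and in the
convex hull (it is a real carbon of the molecule). Coplanar point sets
return the flattened hull — twice the polygon area — because near-planar
all-anti chains are legitimate conformers; colinear sets raise a
degenerate-geometry error.

**Pooled PCA alignment.** Before pooling carbons across conformers, each
conformer is rigidly aligned to its own principal axes (x = widest, z =
flattest spread) with deterministic sign rules (chain runs toward +x, C1
on the +y side). A head-anchored alternative (C1 at origin, C2 along +x,
C3 in the xy half-plane) is available as `mode="head_frame"`, but it was
not adopted as the default: anchoring the carboxyl head lets the flexible
tail propagate isotropically, so the pooled cloud is thick in z
(PC1+PC2 ≈ 0.73 on the synthetic library) and the projection mostly
pictures frame propagation rather than molecular shape. Principal-axes
alignment compares shapes directly and concentrates PC1+PC2 near 0.99
here; the exact fraction is generator-dependent.

Group statistics use a two-factor additive ANOVA (class + position) on
per-conformer records via statsmodels OLS, with Tukey HSD on the class
factor; the position factor is dropped automatically when it has a single
level. The per-conformer observational unit maximizes n; treating lipids
as units is possible by averaging records first.

## Pose analysis

Scores (Glide Emodel, MM-GBSA ΔG) are ingested, never computed.
Convergence filtering precedes seeded equal-count subsampling (without
replacement; a lipid with too few poses raises a shortfall error naming
it). Carboxyl groups are collapsed to the oxygen-pair midpoint.

k-means runs for k = 1..10 with 25 seeded restarts per k (best WSS kept);
cluster labels are canonicalized by lexicographic centroid order. The
elbow candidate is the smallest k where the discrete second derivative of
the WSS curve, `WSS(k−1) − 2·WSS(k) + WSS(k+1)`, drops below a threshold
(default 10,000 — note this is scale-dependent, presuming Å² coordinates
over thousands of poses; it is exposed in the API). The silhouette
candidate maximizes mean silhouette width (k ≥ 2). On disagreement the
silhouette winner is used by default — it is the quantitative criterion of
the two — and both candidates are always reported. All-identical points
yield k = 1 with silhouette undefined.

Score comparisons: two clusters → Mann-Whitney U per lipid class; more →
Kruskal-Wallis plus Dunn's mean-rank post-hoc with tie correction and
Holm adjustment, summarized as a compact letter display (greedy
insert-and-absorb).

## Interaction fingerprints

Commercial fingerprint typing is proprietary, so the typing here is a
documented, configurable lookup-table scheme over heavy-atom pairs within
an inclusive 4.0 Å cutoff: contact (any pair), backbone/side-chain (by
atom flag), polar (pair involves N/O/S), hydrophobic (C/S-only pair with
an aliphatic/aromatic-hydrophobic residue), acceptor/donor (receptor atom
name in a fixed table, ligand atom N/O), charged (side-chain N/O of
ASP/GLU/LYS/ARG/HIS), aromatic (ring atoms of PHE/TYR/TRP/HIS). Because a
pair can satisfy several types, the default cell value aggregates all
typed counts (`count_mode="typed_sum"`); counting each pair once is
available as `count_mode="union"`. Cells are normalized by the lipid's
conformer count, not its pose count, so duplicating poses doubles cells.

## Dose-response

The working ratio is acceptor/donor (520/495), rising with coactivator
recruitment; the direction is a switch. Normalization maps the no-agonist
mean ratio to 0% and the reference-agonist top-concentration mean to
100%. A QC rule flags test wells whose raw 520 nm signal falls below the
mean no-LBD control — the acceptor-collapse signature that can make an
assay unfittable — and excludes them from fits.

4PL fits run on log10 concentration with EC50 parameterized as
log10(EC50), slope bounded in (0, 10], and starting values from response
quartiles. Wald 95% CIs come from the `curve_fit` covariance; EC50
intervals are computed on the log scale and exponentiated, and the EC50
SE uses the delta method. Flat responses and failed optimizations return
flagged fits (NaN EC50) that refuse parameter comparison. Replicate wells
are pooled by default (for balanced designs, fitting replicate means gives
identical point estimates).

Pairwise ligand comparisons are Wald z tests on fitted parameters,
`z = (θ_a − θ_b)/√(SE_a² + SE_b²)`. Under the model's assumptions
(independent homoscedastic errors) the test is calibrated: simulated
type-I error is ≈ 0.05 over 1,000 equal-parameter runs. Comparisons of
fits taken through the full plate pipeline are mildly anticonservative
(~0.07–0.08 measured) because channel noise is multiplicative
(heteroscedastic on the response scale); comparing ligands from the same
plate — the realistic design, since real comparisons share normalization
controls — removes the larger, anchor-correlation component of this
inflation.

Affinity correlations use Pearson's r, with an automatic Spearman
fallback when either vector fails a Shapiro-Wilk normality check.

## Synthetic data

All generators are pure functions of their config (seed included) and
emit their planted truth.

*Pose clouds* place carboxyl midpoints around planted cluster centers
(default two centers 20 Å apart, 2 Å isotropic spread — scaled to a
~20 Å docking box), with cluster choice weighted per lipid class (default
weights echo the reported two-cluster class enrichments: CpFA 60%,
MUFA 45%, SFA 39% in cluster 1), Gaussian per-cluster Emodel means
(−70/−60 kcal/mol, SD 5) and a 10% minimization-failure rate. The default
panel is the study's 14 modeling lipids. Optional straight carbon tails
support fingerprint work. What this does **not** emulate: force-field
energetics, pocket sterics, or any correlation between pose geometry and
score beyond the planted cluster means — so passing recovery tests shows
the analytics recover planted structure, not that real docking data has
such structure.

*Pockets* place named residues (backbone N/CA/C/O plus short side chains,
side chain pointing inward) a fixed offset from chosen cluster centers,
giving planted proximal/distal residue sets; they serialize to standard
PDB and round-trip through Biopython.

*Plates* map true 4PL activation (%) onto a channel ratio between the 0%
ratio (1.0) and the 100% ratio (2.0), then apply a per-well common-mode
gain error (default 5%) shared by both emission channels plus small
independent detector noise per channel (default 1.5%). The common-mode
term is the dominant real-plate noise (dispensing, flash energy, receptor
amount) and is exactly what the ratiometric 520/495 readout cancels;
modeling it as independent per-channel noise would overstate ratio noise
several-fold. The no-LBD control sits at 60% of the 0% ratio, providing
the acceptor floor the QC rule needs. Defaults: 12-step half-dilution
from 100 μM, quadruplicate, truth (lower 0, E_max 60%, EC50 5 μM,
slope 1). FRET photophysics is not modeled.

## Problem sizes

The library-scale analyses run at 50 conformers per lipid (21,450
conformers over all 429 lipids), cluster-recovery checks at 14 lipids ×
30 poses over 50 seeds, plate recovery at 50 simulated plates, and Wald
calibration at 1,000 simulations — sizes chosen so the full analysis
reruns in minutes while keeping every qualitative contrast
well-resolved. The full-budget arithmetic (999 conformers per lipid,
461/371/407 poses per lipid) is reported as arithmetic and exercised by
the subsampling code paths.

## Known limitations

- Conformer ensembles are rotamer-sampled under a hard-sphere model; no
  force field, solvent, or Boltzmann weighting. Absolute descriptor
  values depend on these conventions; only contrasts between classes and
  positions are meaningful.
- The WSS elbow threshold is scale-dependent and must be rescaled for
  coordinates not in Å or very different pose counts.
- Fingerprint typing is a documented approximation of proprietary
  schemes; hydrogen-bond geometry (angles) is not checked.
- Plate-pipeline Wald comparisons across *different* plates inherit
  anchor-correlation anticonservatism; compare within a plate.
- Real docking and wet-lab results (cluster counts per receptor, Table-1
  style EC50/E_max values) depend on unpublished raw data and are not
  reproduced here; the synthetic defaults only mirror their reported
  summary structure.
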