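# Methods

This note documents the models, algorithms, defaults and design choices
behind pharmscreen, and what the synthetic fixtures do and do not establish
about behavior on real data.

## Pharmacophore model

Six feature kinds are detected on 3D molecules: hydrogen-bond acceptors and
donors, negative and positive ionizable groups, aromatic rings, and
hydrophobic clusters. Donor/acceptor/ion typing is SMARTS-driven from
`src/pharmscreen/data/pharmacophore_smarts.tsv`, loaded at first use so the
definitions are auditable and swappable (kind, SMARTS, center mode per row).
The conventions follow common pharmacophore practice:

- **Donors**: N/O/S bearing at least one hydrogen (explicit or implicit),
  including pyrrole-type nH. Direction = heteroatom→H bond vector sum; when
  no explicit hydrogen is present the negated heavy-bond-vector sum stands in.
- **Acceptors**: O with an available lone pair (hydroxyl, carbonyl, ether,
  anionic), sp2/sp3 N excluding amide/aniline/nitrile-type N, pyridine-type
  n, neutral divalent S. Direction approximates the lone-pair direction as
  the negated bond-vector sum at the heteroatom.
- **Positive**: formally cationic atoms without an adjacent counter-charge,
  guanidine/amidine groups, imidazole, primary aliphatic amines (assumed
  protonatable at physiological pH). Center = charged-group centroid.
- **Negative**: carboxylate/carboxylic acid, sulfonate, phosph(on)ate,
  tetrazole, other formal anions. Center = group centroid, e.g. the
  three-atom carboxylate centroid.
- **Aromatic**: 5- and 6-membered aromatic rings from ring perception;
  center = ring centroid, direction = ring normal (sign-free downstream).
- **Hydrophobic**: connected clusters of ≥ 2 carbons/halogens that carry no
  charge, have no charged neighbor, and are not directly bonded to N/O/S.
  The exclusion of heteroatom-bonded carbons keeps, e.g., ethanol free of a
  hydrophobic feature while benzene keeps its full 6-atom ring cluster.
  Cluster size is recorded as the feature's `minsize` metadata.

Within a kind, matches whose atom sets are subsets of another match are
dropped (the bare anion of a carboxylate in favor of the whole group), and
duplicate groups collapse.

Default tolerance radii: 1.0 Å for polar/ionic features, 1.1 Å for aromatic
and hydrophobic — editable per feature, as in interactive practice where
radii are tuned per query.

## Interaction elucidation

Given ligand and receptor feature sets in one coordinate frame, a ligand
feature is enabled iff a complementary receptor feature
(donor↔acceptor, +↔−, aromatic↔aromatic, hydrophobic↔hydrophobic) lies
within a kind-dependent center distance: 4.0 Å for hydrogen bonds, 5.0 Å for
ion pairs, aromatic and hydrophobic contacts. All features are returned with
their enabled flags so disabled ones can be re-enabled interactively.
Receptors parsed from PDB rely on the reader's residue templates for
aromaticity and implicit hydrogens; HETATM ligands read from a complex get
proximity-perceived bonds, so supplying the ligand as SDF/MOL with explicit
bond orders is preferred when available.

## Matching and alignment

Correspondence enumeration is exhaustive over injective kind-compatible
assignments, pruned by the pairwise distance test
|d_query(i,k) − d_conf(j,l)| ≤ r_i + r_k. The pruning is conservative: any
assignment admitting a verifying rigid motion satisfies it (triangle
inequality), so no verified match is lost — checked against a no-pruning
matcher in the tests and the acceptance script. There is no sub-linear
index; at desk scale (up to ~10⁴ conformers) exhaustive matching with
pruning answers in seconds.

Superposition is classic Kabsch on matched feature centers with equal
weights (SVD of the cross-covariance with determinant correction; proper
rotations only). Direction vectors never enter the objective; they are
verified after alignment against a 45° cutoff (configurable), with aromatic
normals compared sign-free. When the matched centers are rank-deficient
(coincident/collinear/planar — common for small ligands whose features
collapse onto two sites) the minimizer is not unique; among the minimizers a
direction-aware candidate is tried (pseudo-points at center + direction,
enumerating aromatic normal signs) before a correspondence is rejected. The
centers-only RMSD remains the reported score and ranking key. Ties break by
(molecule id, conformer id) for deterministic output.

## Shape model

Molecular shape is the solvent-excluded volume: the union of heavy-atom
Bondi vdW spheres morphologically closed with a 1.4 Å probe ball (dilate
then erode) on a 0.5 Å voxel grid. Grid origins snap to the resolution
lattice, giving all grids in a frame a shared global indexing so Tanimoto,
containment and overlap are exact set operations. A single-atom SEV
reproduces the analytic sphere volume to ~3% at 0.5 Å and ~0.3% at 0.2 Å.

Conformers are canonicalized to their principal axes of the heavy-atom
unit-mass second-moment tensor (eigenvalues decreasing along x ≥ y ≥ z),
centroid at the origin, signs chosen to make the third moments along x and y
non-negative with det = +1. The sign rule is ambiguous for symmetric or
degenerate spectra (flagged via `return_info`), so shape search evaluates
all four proper axis flips of each conformer and keeps the best passing one
— the convention then affects only ranking determinism, never hit
membership.

Constraint semantics differ by modality, deliberately:

- **Shape-first (strict)**: the entire inclusive volume must lie inside the
  molecular shape and the shape must not intersect the exclusive volume;
  survivors rank by descending Tanimoto to the query ligand shape. An
  optional pharmacophore filter then requires every enabled query sphere to
  contain a same-kind conformer feature in the shape-aligned pose, with no
  re-alignment.
- **Pharmacophore-first (filter)**: after RMSD alignment, at least one
  heavy-atom center must fall in an inclusive-occupied voxel and none in an
  exclusive-occupied voxel.

Constraint tolerances erode (positive) or dilate (negative) the stored
volume by whole voxel shells with a Euclidean-ball element; eroding the
exclusive volume admits more hits, monotonically. A receptor-derived
exclusive constraint is the receptor SEV shrunk by the tolerance (in Å).

**Strict ⇒ filter**: if an inclusive constraint is a ligand shape eroded by
less than the smallest heavy-atom vdW radius (≈ 1.5 Å), every heavy-atom
center lies at least its own vdW radius deep inside the SEV, so the eroded
constraint retains atom-center voxels and any pose passing the strict check
passes the filter check. Deeper erosion hollows the constraint into
interstitial volume that contains no atom center, and the two semantics
genuinely diverge; the property tests therefore sample erosion depths in
(0.25, 1.0) Å, the provable regime.

## Library construction

From SMILES: parse → keep the largest covalent component (salt stripping) →
canonicalize and drop duplicate canonical SMILES (first record wins) →
rule-based pH 7.4 protonation (carboxylic/sulfonic/phosphonic acids
deprotonated, aliphatic amines and amidine/guanidine imine N protonated) →
distance-geometry embedding (ETKDG) with UFF relaxation, keeping up to
`max_confs` (default 10) conformers after a greedy 0.5 Å heavy-atom-RMSD
diversity prune ordered by UFF energy. Embedding seeds derive
deterministically from the library seed and record index, making builds
bit-reproducible.

From SDF: coordinates are trusted as conformers; consecutive records with
identical name and canonical topology group into one entry (the grouping
rule for per-molecule hit caps); acidic protons are normalized, but
protonation that would require placing new atoms is not attempted on fixed
coordinates; flat geometries (all heavy-atom z ≈ 0 with > 3 heavy atoms) are
flagged as suspect 2D input.

Properties (molecular weight, rotatable bonds, Crippen logP, TPSA, aromatic
ring count) come from standard descriptors on the implicit-hydrogen graph;
HBA/HBD counts reuse the pharmacophore SMARTS so filters and features agree.
Libraries persist as a directory: `manifest.json`, a gzipped SDF shard of
conformers tagged with molecule/conformer ids, and `properties.tsv`.
Features are recomputed on load (they are deterministic in the
coordinates); shape grids are computed on demand and cached.

## Screening, caps, metrics

Property range filters are closed intervals applied to entries before the
structural search (equivalent to post-filtering, tested as such). Hit caps
apply in order: best poses per conformer, best conformers per molecule,
total hits — all stable under the active sort key (RMSD ascending or shape
similarity descending by default; molecular weight and rotatable bonds also
available, either direction).

EF and F1 are computed over distinct molecules, not conformers — counting
conformers would multiple-count each retrieved active. The F1 reported by
default is the standard harmonic mean of precision and recall; a geometric
mean variant is available (`f1_mode="geometric"`) since both conventions
appear in the screening literature. EF ranges from 0 to N/A (all-active
hits); returning the whole library gives EF = 1.

Energy minimization against the receptor is out of scope; an adapter hook
(`external_minimizer_hook`) re-sorts and filters hits by affinity and
minimized-RMSD values supplied by an external scorer.

## Synthetic fixtures: what they show

`make_planted_library` plants actives as rigidly displaced copies of a
rigid template compound (4-hydroxybenzamide: aromatic ring + phenolic donor
+ carbonyl acceptor define the default 3-feature query) with per-atom
Gaussian noise clipped at min(3σ, 0.4) Å — far inside the tolerance radii,
so actives match by construction. The default query is directional only on
the aromatic ring normal: single-bond donor/acceptor vectors can rotate
past the 45° cutoff at sub-radius displacements, which would void the
construction guarantee. Decoys are purely aliphatic molecules verified at
generation time to contain no aromatic ring, so they can never map the
query's aromatic feature. Default composition, 10 actives + 90 decoys at
σ = 0.05 Å, gives EF = 10 at perfect retrieval.

`make_toy_complex` places a serine hydroxyl 2.8 Å outside the template's
phenol oxygen, a phenylalanine ring 3.8 Å above its aromatic ring, and a
glycine plus two waters far away, with an internal geometric assertion that
the deliberately non-interacting ligand features (amide donor, carbonyl
acceptor) stay > 5.5 Å from every receptor polar atom. The ground-truth
enabled set (phenol donor + phenol acceptor + aromatic + hydrophobic) is
thus fixed by construction.

These fixtures establish correctness of the machinery — matching
completeness, alignment optimality, semantics, determinism, metric
arithmetic — under controlled geometry. They do not emulate conformational
flexibility of actives, property-matched decoys (DUD-E style), tautomer or
stereoisomer ambiguity, or receptor-scale shape constraints, so passing
tests bound implementation behavior, not expected enrichment on real
benchmarks. Problem sizes in the tests and acceptance script (libraries of
tens of molecules, hundreds of generated constraint cases, thousands of
random placements) are chosen to exercise every code path in about a minute.

## Numerical choices

- Coordinates in Å everywhere; voxel resolution 0.5 Å (configurable).
- Radii/cutoff tables ship as text data; unlisted elements fall back to a
  1.7 Å vdW radius.
- Sphere containment uses a 1e-9 slack; RMSD equality ties break by ids.
- PDB parsing: model 1 only, highest-occupancy altloc (first on ties),
  first copy of a duplicated ligand residue unless an index is given.
- Erosion can empty a grid; empty inclusive constraints are vacuously
  satisfied in strict mode and skipped in filter mode; Tanimoto of two
  empty grids is defined as 0.
- Gzipped exports write a fixed mtime so repeated runs are byte-identical.

## Known limitations

- Feature typing operates on whatever protonation/bond orders the input
  carries; HETATM ligands from PDB complexes get proximity bonds.
- No tautomer or stereoisomer enumeration; protonation is a small fixed
  rule set, not a pKa model.
- Inertia canonicalization is undefined for < 3 non-collinear heavy atoms;
  such conformers are skipped in shape search.
- The strict/filter semantics relationship holds only in the erosion regime
  described above.
- Exhaustive matching scales combinatorially in query features with equal
  kinds; queries beyond ~6-7 features of one kind are slow (and, as
  interactive practice shows, rarely useful).
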