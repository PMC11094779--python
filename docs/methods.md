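# Methods

This note documents the models, parameters, numerical choices and
limitations of `gpcrtherm` the way a maintainer would want them recorded:
what is computed, why the defaults are what they are, and what the
synthetic benchmarks do and do not demonstrate.

## Structure handling

A receptor model is reduced to a flat list of heavy atoms. `load_structure`
keeps every ATOM/HETATM record (waters and ligands included) so that
cleaning is an explicit, auditable step; alternate locations collapse to
the highest-occupancy conformer, ties broken by altloc label order.
`clean_structure` keeps the standard amino-acid heavy atoms of a single
chain: waters, ligands, other chains and hydrogens are removed. Hydrogens
are always discarded — AlphaFold-style models are heavy-atom, and dropping
hydrogens keeps signatures independent of whether a model was protonated.
Author (PDB) residue numbering is used verbatim; mutation lists refer to
those numbers. Loop excision is deliberately *not* performed here: if a
model's low-confidence loops should be excluded, that is the data
preparer's choice, made before the file reaches this package.

The residue's *geometric center* is the unweighted mean of all its heavy
atoms (backbone plus side chain). Truncated coordinate records are
rejected with a format error rather than silently skipped.

## Graph-based structural signatures

The wild-type residue environment is the set of heavy atoms within radius
`r` of the residue's geometric center, the residue's own atoms included —
they are the mutation's immediate chemistry. The default `r` = 10 Å is a
package choice (configurable): large enough that the 6 Å pair cutoff grid
is not starved at the sphere's edge, small enough that the signature stays
local to the site.

Atoms carry one or more of eight pharmacophore classes — hydrophobic,
positive, negative, H-bond acceptor, H-bond donor, aromatic, sulfur,
neutral — assigned by exact lookup on (residue name, atom name) in a
packaged, versioned CSV table built from standard chemistry (aromatic ring
carbons are also hydrophobic; carboxylate oxygens are acceptor+negative;
PRO backbone N is not a donor; and so on). Unknown atoms degrade to
{neutral} with a warning rather than aborting a run.

For every unordered class pair (C1, C2) and every cutoff d in the grid
(default 2.0–6.0 Å, step 0.5), the signature counts unordered atom pairs
{a, b} with interatomic distance ≤ d where one atom carries C1 and the
other C2. The counts are cumulative in d by construction. A pair
contributes to every class pair it satisfies, but only once per class pair
even when both atoms carry both classes. Two readings of the published
feature names were possible — the cutoff bounding the pair distance, or
bounding the distance to the mutation site; the package uses the
pair-distance reading, which matches the cutoff-scanning contact-graph
construction the features are named after, and leaves the environment
radius as the separate parameter `r`.

The optimized implementation (k-d tree pair query + per-class-pair sorted
distances) is checked for *exact* equality against a brute-force O(n²)
enumeration in the test suite; counts are also checked to be invariant
under rigid rotation and translation and monotone in the cutoff.

The mutant side is represented only by the pharmacophore-change vector
`PChange = p_mt − p_wt`, where `p` tallies (heavy atom, class) memberships
over a residue type's canonical atoms (backbone included; it cancels in
the difference). No mutant structure is built or needed.

## Auxiliary features

- **Substitution matrices**: BLOSUM62 and PAM30, loaded from biopython's
  packaged tables, symmetric lookup.
- **Amino-acid pair matrices** (AAindex2 flat-file dialect, parsed by the
  package): a genetic-code matrix keyed `BENS940104` and an α-helix-class
  substitution table keyed `LUTR910108`. The packaged file
  (`data/aaindex2_synthetic.txt`) contains *synthetic reconstructions*:
  the genetic-code matrix is computed from the standard codon table
  (maximum base matches between the two residues' codon sets, 0–3), and
  the helix table from Pace–Scholtz helix propensities
  (−mean propensity − |propensity difference|, symmetric). They preserve
  the semantics of the published entries — genetic-code interconvertibility
  and helix substitution compatibility — without reproducing their exact
  values; swap in the real flat file to use the published numbers.
- **Relative solvent accessibility**: Shrake–Rupley SASA (1.4 Å probe,
  biopython backend) divided by the residue type's theoretical maximum
  (Tien et al. 2013, packaged). Values slightly above 1 are possible for
  exposed conformations; a *lone* residue scores well above 1 because the
  reference buries peptide-bond surface.
- **Residue depth**: mean distance of the residue's heavy atoms to a
  solvent-accessible surface dot cloud (Fibonacci-sampled spheres of
  radius vdW + 1.4 Å, occlusion-pruned, 60 points/atom). A dot-surface
  mean-distance is sufficient for a burial measure; no MSMS-style
  triangulated molecular surface is required.
- **Topology flags**: from a per-residue annotation CSV when supplied;
  otherwise a z-slab rule for membrane-oriented structures (membrane
  normal = z, extracellular up): `mem` = 1 iff |z| ≤ half-width (default
  15 Å, the approximate hydrophobic half-thickness of a bilayer);
  `non_cytosol` = 1 iff z ≥ −half-width.
- **Special-residue indicators**: FromPro, ToAla, FromGly, ToPro. These
  stand in for "special amino acid" substitution scores: proline's ring
  rigidity and glycine's flexibility make those substitutions
  qualitatively different, and alanine is the alanine-scanning default.
- Further families (contact counts, normal-mode or potential-energy
  terms) plug in through the `FEATURE_PROVIDERS` registry without
  touching the pipeline.

## Dataset handling

Mutation tables from several sources are merged with the redundancy key
(UniProt accession, position, mutant residue): the first-listed source
wins and order is stable. The key deliberately excludes the wild-type
residue; records that share a key but disagree on the wild type are a
data *conflict* and raise, rather than being silently merged. The blind
split is a seeded uniform draw of round(fraction·n) records (default
fraction 0.13), disjoint at mutation level; receptors may appear on both
sides, mirroring how curated GPCR stability data are actually structured.

Featurization verifies the stated wild type against the structure before
any cached per-site quantity is reused, and is a pure function of
(records, structures, config): identical inputs give bit-identical
matrices. Strict mode aborts on any failing record; lenient mode drops
failures into a run report.

## Learning

Greedy forward selection starts from the empty set; each round scores
every remaining candidate joined to the current set by the Pearson
correlation of pooled out-of-fold predictions under k-fold CV (default
k = 10), fixes the best candidate, and stops at the first round with no
strict improvement (ε = 0). Numerical choices worth recording:

- the fold partition is drawn once per selection run, so candidate scores
  are comparable across rounds;
- ties between candidates break by column order, making selection fully
  deterministic given (data, config, seed);
- a constant out-of-fold prediction vector leaves Pearson undefined; it
  is flagged NaN and ranked below every real score;
- MSE is recorded at every step but never drives selection. Selecting on
  correlation alone can worsen MSE while improving rank quality — the two
  metrics answer different questions and this package follows the
  correlation-only rule.

Regressors: random forest, extra-trees, gradient boosting, XGBoost; 300
estimators each, every other hyperparameter at the library default, seed
exposed (default 42). Models persist as a joblib bundle plus a JSON
sidecar (algorithm, features, seed, format version). Ranking sorts
predictions descending with stable ties; positive values are read as
stabilizing. `feature_importance` exposes impurity and permutation
importances and accepts a callable for external attribution engines
(e.g. SHAP-style explainers).

## Evaluation

Regression: Pearson r, MSE, tie-corrected Kendall τ (τ-b), Spearman ρ.
Classification-by-regression: a neutral band [lo, hi] (boundaries
*included* in neutral — the published wording "below/above" leaves the
boundary open, and the closed-neutral convention is the conservative
reading), three-way labels, accuracy / generalized multiclass MCC /
support-weighted F1 (degenerate single-class MCC is defined as 0 with a
warning). The binary stabilizing rule maps positive → 1, everything else
(zero included) → 0. The band scan evaluates symmetric bands
t = 0.1, 0.15, …, 3.0 (59 bands) and flags the MCC argmax; in
benchmarking, each method's predictions are classified with that method's
own band while the truth uses the band under scan. Asymmetric bands are
not scanned.

## Synthetic data and what the tests show

`make_helical_bundle` builds an ideal parametric α-helix per chain
segment (1.5 Å rise, 3.6 residues/turn; N/CA/C/O on phase-shifted
co-axial helices, consecutive Cα–Cα ≈ 3.83 Å) with each side chain
reduced to a single Cβ pseudo-atom carrying the residue's full
pharmacophore profile, helices parallel on a ring, bundle axis = z and
centered so the z-slab topology rule applies. `plant_labels` draws
y = Σ wᵢ·z(fᵢ) + N(0, σ²) over standardized (population σ) feature
columns, giving a closed-form recovery oracle.

The planted-signal study conditions are: weights (2.0, 1.0, −1.5) on
three real featurized columns — `Hydro:Hydro-4.00`, `BLOSUM62`, `rsa`,
one per feature family — noise σ = 0.5 °C, and 30 independent
standard-normal decoy columns. Independent decoys are used because the
cumulative cutoff grid makes neighboring signature columns near-duplicates
(r > 0.95) of the planted one; with such decoys the benchmark would test
identifiability of collinear features rather than the selection protocol.

Problem sizes in the default test run are chosen for a single-CPU budget
and stated here as the package's own configuration: the recovery study
runs one seed at 200 mutations (174 train after the 13% split) and the
pure-noise guard one seed at n = 300 with 50 candidates; both run one
full greedy selection with 10-fold CV and 300-tree forests.
`scripts/acceptance.py` repeats both at the caller's seed.

What passing shows: the signature implementation is exactly correct
against enumeration; the selection + forest pipeline recovers a known
sparse linear signal embedded in real featurized columns and does not
manufacture correlation from noise; the full pipeline is deterministic to
the byte. What it does not show: performance on real receptors. The
bundles have no loops, no rotamers, no lipids, a single conformational
state and Cβ-collapsed side chains; planted labels are linear, whereas
real ΔTm surfaces are not; and the packaged AAindex-format matrices are
reconstructions. Accuracy on experimental GPCR data must be established
with curated mutation tables and real structure models.

## Known limitations

- Single-chain, single-state analysis; no interfaces, ligands or
  oligomers in the environment graph.
- UniProt-to-structure numbering is assumed to be the identity (true for
  full-sequence models); an offset field covers renumbered inputs, but no
  alignment-based mapping is attempted.
- The z-slab topology heuristic requires a membrane-oriented model;
  non-oriented structures need an annotation file.
- Residue depth uses a dot-cloud surface; absolute values differ from
  MSMS-based depth by a fraction of an ångström, consistently.
- XGBoost determinism holds for fixed library versions on one platform;
  cross-platform bit-identity is guaranteed only for the sklearn
  ensembles.
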