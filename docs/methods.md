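# Methods

This note records the models, numerical choices and limitations behind
`coatmap`, in the order the pipeline applies them.

## Structure model and PDB handling

Structures are chains → residues → atoms with author residue numbering
(seq id + insertion code) as the identity used everywhere; interface
tables for real assemblies cite author numbering, so sequential
renumbering is never implied. Parsing (via Bio.PDB) drops waters,
hydrogens and non-MSE HETATM groups; MSE is read as MET; other
nonstandard residues become UNK and are excluded from classification
(reported, never silently dropped). Alternate locations resolve to the
highest-occupancy conformer, first-in-file on ties. The C-alpha-only flag
is per chain, not per file, so mixed-resolution models are handled.

Van der Waals radii are element-keyed (C 1.87, N 1.65, O 1.40, S 1.85,
P 1.90, Se 1.90 Å — a Chothia-style united-atom protein set); CA atoms of
C-alpha-only chains get a united-residue radius of 1.87 Å. The coarse
model thus treats each residue as one sphere centred on its C-alpha; the
probe radius (3.5 Å), not the sphere radius, carries the
coarse-graining, matching how accessibility is computed for
low-resolution models.

## Solvent accessibility

Shrake–Rupley quadrature with a deterministic golden-spiral point set in
a fixed orientation (default 960 points/atom). Determinism was preferred
over random sampling so that every downstream number is bit-for-bit
reproducible at fixed `n_points`. Accuracy: the isolated-sphere closed
form 4π(r+probe)² is reproduced essentially exactly (an isolated sphere
has no occluded points) and partially occluded geometries converge as the
point count grows. Quadrature anisotropy — sensitivity of the exposed
count to rigid-body orientation — is below 0.5% of a residue's total
inflated-sphere area at 960 points (measured 0.34% max on the bundled
complex). Note that expressing the same deviation relative to a nearly
buried residue's own ASA can look arbitrarily large, because the
denominator approaches zero; the total-area scale is the one the
quadrature controls.

Relative accessibility divides residue ASA by a reference maximum. The
all-atom (1.4 Å) reference is the theoretical Gly-X-Gly maximum-ASA scale
of Tien et al. (2013); it is configurable because published analyses
differ in this choice and the 7%/10% thresholds inherit its meaning. For
the C-alpha regime a single reference value is computed on demand from an
extended, collinear 3.8 Å-spaced three-sphere C-alpha trace; in a
united-sphere model all residue types share this geometry, and the value
is informational only because the coarse-regime criterion operates in
absolute Å².

## Interface detection

All-atom rule: relative accessibility < 7% in the complex AND > 10% in
the isolated chain, both strict. C-alpha rule: absolute C-alpha ASA below
a buried cutoff in the complex AND above an exposed cutoff in isolation,
cutoffs per residue type.

The cutoff table is calibrated by pooling, over a corpus of all-atom
complexes, pairs of (all-atom relative accessibility at 1.4 Å, C-alpha
ASA at 3.5 Å of the same residue with the whole complex reduced to CA
traces), fitting a monotone non-decreasing (isotonic) regression per
residue type and reading it at 7% and 10%. Isotonic regression was chosen
because the physical relation is monotone but has no parametric reason to
be linear, and the fit is reproducible from any corpus without tuning.
Types with fewer than 50 training pairs (configurable) fall back to the
pooled all-type fit and are flagged. Degenerate flat fits that would
equate the two cutoffs are widened by 1e-6 Å² and flagged, preserving the
buried < exposed invariant.

Assemblies are decomposed into per-chain subcomplexes (chain + ≤5 Å
near neighbors, inclusive boundary, all C-alpha atoms considered); each
chain's interface is detected inside its own subcomplex treated as an
independent structure. Chains beyond occlusion range of everything yield
empty interfaces in both regimes.

On synthetic complexes the coarse regime recovers the all-atom detection
with median per-chain F1 around 0.6–0.75. The absolute number depends on
the evaluation batch: detected interfaces are small (a few residues per
chain), so per-chain F1 is strongly quantized and batch medians vary.

## Conservation

Homologue filtering keeps hits with identity > 30% and coverage > 70% of
the query, strict. Identity counts identical pairs over aligned columns
excluding gap-gap pairs; coverage is the aligned span over the full query
length — the common PSI-BLAST-style conventions, stated here because the
thresholds inherit them.

The conservation score is a surrogate with the one property downstream
analysis relies on: *lowest score = most conserved*. Per column covering
the target sequence, amino-acid frequencies weighted by Henikoff–Henikoff
position-based sequence weights (gaps count as a symbol for weighting,
are excluded from frequencies) give a Shannon entropy; entropies are
z-normalized across positions (all-identical alignments score 0 by
convention). Columns over 50% gapped are scored but flagged and excluded
from group means. Externally produced conservation grades with the same
convention can be imported in place of the surrogate for real-data runs.
Bayesian phylogeny-aware rate inference is deliberately out of scope.

Two score scales coexist: the z-normalized score for within-family
comparisons (interface vs surface), and the raw entropy mean for
across-family comparisons (the radial-layer ordering), since
z-normalization forces every family's mean to zero.

The interface-vs-surface comparison partitions a chain into interface
(membership takes precedence), non-interface surface-exposed (isolated
relative accessibility > 10%) and buried, then reports group means, the
difference (interface − surface; negative = interface more conserved) and
a seeded 10,000-resample bootstrap percentile CI. Single-member groups
run with a warning and a degenerate-wide CI.

## Genetic distances, trees, mirror correlation

Pairwise distances correct the observed fraction p of differing
comparable (non-gap in both) columns: Poisson d = −ln(1−p) or Gamma
d = α((1−p)^(−1/α) − 1). At p ≥ 0.95 the distance saturates to a finite
sentinel (d = 10, flagged) so Pearson correlations stay defined. These
are surrogates for likelihood machinery (ML tree search, empirical
substitution matrices) that the distance-correlation analysis does not
require; externally computed distance matrices (PHYLIP square) and trees
(Newick) can be imported for parity with such tools.

Neighbor joining uses the standard Q criterion with a deterministic
tie-break (lowest index pair) and clamps negative branch lengths to zero,
counting both events. On additive matrices the reconstruction is exact
(verified against an independent implementation); estimated matrices need
not be metric and triangle violations are tolerated.

Mirror-tree correlation restricts two matrices to their common species
(≥ 4 required), vectorizes upper triangles in a common order and reports
Pearson r. Significance comes from a one-sided label-permutation test
(rows and columns permuted together; p = (1 + #{r_perm ≥ r_obs}) /
(1 + n_perm); default 9,999 permutations, 999 in batch runs). One-sided
because positive co-evolution is the hypothesis. A caveat observed during
validation: with strongly tree-structured matrices the permutation null
is mildly liberal (≈14% rejections at the 5% level in one batch of
independent-tree pairs), a known property of Mantel-style tests under
autocorrelation; under an exchangeable null (independent random matrices)
rejection rates sit at the nominal level. Interpret borderline p-values
on real families accordingly — the unrelated-pair baseline the batch
interface supports is the more robust calibration.

## Synthetic study systems

The complex generator builds ideal α-helices (radius 2.3 Å, rise 1.5 Å,
100°/residue) with one united side-chain bead per residue (radius
2.0–2.7 Å, extension 1.9–4.0 Å, scaled with residue size; glycine none)
plus a carbonyl-like backbone bead, packed side by side at 9.0 Å axis
separation — roughly the knobs-into-holes separation of natural helix
pairs given the slightly slim reduced side chains. Clashes across chains
are resolved deterministically by retracting the offending side beads
(backbone clashes raise an error). Ground-truth interface labels use a
5 Å inter-chain heavy-atom contact criterion chosen to be independent of
the accessibility detector, so detector tests are non-circular. The
strict dual criterion detects the deeply buried *core* of that contact
set (observed precision ≈ 1, sensitivity well below 1): contact-based
and burial-based interface definitions genuinely differ, on real
structures as here. A bead-lattice geometry (extended chains on a grid)
is available for flatter contacts.

Sequence evolution follows an equal-exchangeability 20-state model: on a
branch of length t, a site with rate r experiences substitution events as
a Poisson process with intensity (20/19)·t·r, each event drawing the new
state uniformly from all 20 states, giving the closed form
P(differ over path d) = (19/20)(1 − e^(−(20/19)d)) used as the
generator's own oracle. This matches the Poisson distance estimator by
construction — deliberately, so parameter-recovery tests have exact
expectations. Site classes multiply rates per site (contiguous blocks or
an explicit per-site assignment); a family-wide scale models radial
layers of the assembly (cargo-proximal families faster). Species trees
are generated by sequential random joins with i.i.d. exponential branch
lengths (mean 0.08 substitutions/site), giving 16-taxon pairwise path
lengths of roughly 0.1–1.0 — divergent enough to be informative, far from
saturation. All generators are pure functions of (scenario, seed).

What the synthetic systems do **not** emulate: real side-chain packing
and secondary-structure diversity, indels (alignments are gapless; gap
handling is tested with masked columns), among-site rate correlation,
non-uniform amino-acid composition, and lineage-specific rate shifts.
Passing tests therefore demonstrate that the machinery recovers signals
that are present by construction, not that real coats have those signals.

## Problem sizes

Defaults used by the test suite and the acceptance script: two-chain,
30-residue complexes (≈ 180 atoms all-atom); 30 training and 20 held-out
complexes for calibration studies; 16-taxon families of 300–1000 sites;
100 replicates for recovery rates; 999 permutations per significance
test. These sizes give stable statistics while keeping a full run on one
CPU within a couple of minutes.

## Pipeline

One YAML config drives structures → cutoffs → interfaces → conservation →
mirror correlation. Every stage persists standard-format intermediates
(PDB, TSV, FASTA, Newick, PHYLIP, JSON) in the run directory; stages
communicate only through those files. The report carries provenance
(config hash excluding the output path, package version, seed) and no
timestamps, so identical configs produce byte-identical reports. All
stochastic steps (bootstrap, permutation, simulation) take the config
seed.
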