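# Methods

This note documents the models, conventions, numerical choices, and
known limitations behind `naassess`. Everything stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is imported
from external result tables except where explicitly marked as published
summary statistics used as inputs.

## Structure model and correspondences

Structures are chains → residues → atoms with author residue numbering
(1-based) as the authoritative coordinate; insertion codes order
alphabetically. Polymer type is inferred from residue-name vocabulary
(A/C/G/U → RNA, DA/DC/DG/DT → DNA, the 20 amino-acid codes → protein,
anything else → ligand) because predicted model files often lack entity
records. Alternate conformers are collapsed to the highest-occupancy
atom. Parsing and writing go through gemmi (PDB and the mmCIF
`atom_site` category).

Sequence-mode correspondences match chain id (optionally through a
supplied chain map) plus residue number and insertion code; reference
residues without atoms are excluded, so a predicted pair touching an
unresolved reference nucleotide can never count for or against a score.
Structural mode derives the pairing from the sequence-independent
aligner and is limited to single-chain inputs.

For homo-oligomers the model→reference chain assignment is a genuinely
open question; we search chain permutations within sequence-identity
classes for the assignment maximizing global lDDT, exhaustively for up
to 8 identical chains and greedily (seed superposition, then Hungarian
assignment on chain centroids) beyond that, with a lexicographic
tie-break so results are deterministic.

## Global metrics

All four metrics use representative atoms (C4′/CA) except lDDT, which
uses every heavy atom.

**d₀ conventions.** Nucleic acids: `d₀ = 0.6 √(L − 0.5) − 2.5` for
L > 30, floored at 0.3 Å (the floor governs all shorter chains).
Proteins: `1.24 ∛(L − 15) − 1.8`, floored at 0.5 Å. TM-score and GDT_TS
are always normalized by the reference length, so missing model residues
cost score.

**Superposition search.** TM-score and GDT_TS maximize over rigid
superpositions found by fragment seeding with iterative refinement: seed
windows of several lengths are placed at stride 1 for chains of ≤ 40
residues and stride L/10 beyond, and all windows are refined in parallel
(batched Kabsch via batched 3×3 SVD) under a distance-cutoff schedule
halving from 8·d₀ to d₀ over up to 20 iterations. We chose dense
seeding for short chains after measuring that sparse seeds can sit
~0.01 TM units below an exhaustive-seed search precisely in the short,
strongly-perturbed regime the test fixtures occupy; with dense seeds the
implementation agrees with the exhaustive-seed oracle to machine
precision on ≤ 30-residue cases while staying ~10 ms per call.

**GDT_TS** runs three phases per threshold: seeded refinement with a
shrinking selection cutoff (4t → t, coverage always counted at t), a
parallel peeling phase (drop the worst residue one at a time from every
phase-1 selection, polishing on the inside set after each step), and,
for n ≤ 12, exact enumeration of every residue subset of size ≥ 3 in a
single batched superposition call. GDT_TS is reported on 0–1 for
uniformity with TM and lDDT; the CLI offers the traditional percentage.

**lDDT** uses inclusion radius 15 Å, thresholds {0.5, 1, 2, 4} Å,
same-residue pairs excluded, and a steric penalty: a reference atom pair
whose model counterpart is closer than (vdW sum − 1.5 Å) is unpreserved
at every threshold. Pairs already violating that contact distance in
the reference — covalently bonded atoms, for instance — are exempt, so
the penalty punishes clashes the model introduces, never chemistry the
reference itself contains. The vdW table is a fixed element → radius
map (C 1.70, N 1.55, O 1.52, P 1.80, S 1.80 Å, default 1.70).

**Sequence-independent alignment** ("TM-align score"): initial
alignments from gapless threading at a coarse offset grid, terminal and
central fragment seeds, and (for equal lengths) the identity pairing;
each is iterated by superposing on the current alignment, building the
TM-weighted similarity matrix, and realigning with order-preserving
dynamic programming (gap −0.6, free end gaps) until the alignment
repeats. The three best candidates plus the identity pairing are
re-scored with the full seeded superposition search, which guarantees
the relaxation property: the score is never below the TM-score of the
fixed sequence correspondence. Scores are normalized by the second
structure's length. On 40-residue random coils the null distribution
stays below 0.3 (mean ≈ 0.08), comfortably separating genuine template
hits.

## Base pairs

Canonical pairs are A–U/A–T, G–C, and wobble G–U. The geometric
annotator (a deliberately simple, testable stand-in for full-featured
annotation engines; pre-computed annotations can be ingested instead)
requires complementary identity, N1–N3 donor–acceptor distance ≤ 3.5 Å,
base-plane angle ≤ 30°, and C1′–C1′ separation 10.4 ± 1.5 Å; each
residue joins at most one canonical pair, closest nitrogen distance
winning. Detected pairs failing the identity test are recorded as
non-canonical, matched by nucleotide identity only.

Topology is evaluated over intramolecular canonical pairs in global
residue order (chains concatenated). Crossing uses the symmetric
interleaving relation — (i,j) crosses (k,l) iff `i<k<j<l or k<i<l<j` —
so both members of a pseudoknot are crossed; a pair is a singlet when
neither stacked neighbor (i+1, j−1) nor (i−1, j+1) exists.
Intermolecular canonical pairs form their own class and are excluded
from crossing/singlet analysis, since sequence order across chains is an
artifact of chain ordering.

F1 conventions, applied uniformly to base-pair classes, interface
contacts, and externally supplied motif annotations: prediction and
target both empty → null (no score, excluded from means); target empty
but prediction not → 0 (overprediction penalty); no submission → 0.
Across models and references the best score is kept, where a null beats
any number (correctly predicting "no interaction" is the best possible
outcome).

## Interfaces, ligands, degenerate models

Contacts are inter-chain residue pairs with any heavy-atom distance
strictly below 5 Å. ICS is the contact-set F1, IPS the Jaccard
coefficient over interface residues, i-lDDT the lDDT restricted to
reference atom pairs spanning different chains (steric penalty
retained). For hybrid complexes, per-interface scores are combined as a
residue-count-weighted mean over NA–NA and NA–protein interfaces only.

Ligand pockets are the nucleotides with any heavy atom within 4 Å of the
ligand in the reference. Reported per model: i-lDDT over NA↔ligand atom
pairs, lDDT over pocket-nucleotide atom pairs, and the pocket RMSD after
superposing pocket atoms. When only half a dimeric pocket can be
predicted, scores are normalized by the better-scoring target
half-pocket and capped at 1; the choice of "better half" (max) is our
resolution of an underdetermined convention.

A model "predicts no interaction" when it has zero inter-chain contacts
at 5 Å, or when two chains' centroids coincide within 1 Å and more than
half of their atoms clash (< 2 Å to the nearest atom of the other
chain). Such models are flagged for exclusion review, never silently
edited; pipeline exclusions are an explicit (group, target) list.

## Stoichiometry and symmetry

Chains cluster into entities at ≥ 95% sequence identity (edit-distance
based), tolerating minor construct mutations; labels are copies in
descending count ("A4B2"). Symmetry detection works on P/CA positions:
candidate groups are every Ck with k | n and every Dk with 2k | n
(k ≥ 2). Trial axes are the three principal axes of the chain-centroid
cloud; each group element is applied about the best axis and the
structure is matched to itself under the optimal chain permutation
(Hungarian assignment on rotated centroids), the fit error being the
mean RMSD over all non-identity elements. Among candidates within the
10 Å cutoff, selection is by most chains involved, then most symmetry
elements (|Cn| = n, |Dn| = 2n), with dihedral preferred on exact ties —
encoding the D4-over-C8 precedent. C1 is the universal fallback.

A scale caveat follows from the literal selection rule: for very small
protomers (a 12-nt hairpin), the spurious dihedral flip of a cyclic ring
can fit inside 10 Å and the most-elements rule then upgrades C6 to D3.
Real targets and the generator's default protomers (≥ 8-pair stems,
~25 Å extent) misfit such flips by far more than the cutoff, so the rule
behaves as intended; the recovery tests therefore use realistically
sized protomers, and that is a statement about assembly scale, not a
tuned threshold.

## MSA depth

Pairwise identity ignores columns gapped in both rows; gap-vs-residue is
a mismatch; comparisons are case-insensitive with T ≡ U and N matching
nothing. A sequence's weight is the number of sequences with identity
strictly above 0.8, including itself — the literal "other sequences"
reading yields weight 0 (division by zero) for any unique sequence, so
the include-self convention standard in MSA-weighted structure
prediction is used. Neff = Σ 1/wₛ, giving 1 ≤ Neff ≤ n, invariant to
row order, dual-gap columns, and whole-alignment duplication.

## Ranking

Per (group, target, metric), the best value over up to 5 models and all
references is kept, metrics decoupled. Z-scores per (target, metric) use
one trimming pass: with initial mean m₀ and sample SD s₀ (ddof = 1),
scores ≤ m₀ − 2s₀ are set aside, statistics are recomputed from the
remainder, and every group — including the outliers — is standardized
against the trimmed statistics; s = 0 gives all-zero Z. Trimming is per
target-metric (not pooled across metrics), and only the low side is ever
trimmed. Category combinations use the weights in the README; when a
group's model has no scoreable value for an interface or pocket
component, that component is omitted and the remaining weights
renormalized, with the row flagged.

For the summed ranking, same-sequence targets form one scoring unit
(best Z in the set counts), negative Z-scores floor at zero, and groups
scoring fewer than 60% of a category's scoring units (counted after
grouping — the natural denominator once units exist) are excluded.
Confidence intervals are central 68.2% percentile intervals from 1,000
bootstrap replicates resampling scoring units with replacement,
seeded and reproducible. On Normal synthetic contributions the interval
half-width matches the closed-form standard error of a resampled sum
(√k × sample SD) within a few percent, averaged over seeds.

## Templates and era comparison

The best template for a target is the candidate released strictly before
the deadline with the highest sequence-independent alignment score,
ties broken by candidate id; candidate pools are user-supplied
directories plus a dates CSV — there are no live database queries.
Improvement records (best predicted score minus best template score) are
compared between eras or predictor classes with a two-sample t-test,
Welch by default (pooled variance by flag), with record-level inclusion
flags for curation rules such as excluding human-designed targets. A
consistency check reconstructs the test from published summary
statistics (n = 31, mean 0.027, SEM 0.014 vs n = 34, mean 0.060,
SEM 0.016) and obtains p ≈ 0.126, bracketing the printed 0.13 given
input rounding; this validates the statistical machinery, not a
particular dataset.

## Synthetic data: what it emulates and what it does not

The generator produces coarse-grained nucleotides — P, C4′, C1′, the
pairing nitrogen (N1 purines / N3 pyrimidines), and a base-plane atom
C2 — from a sequence plus dot-bracket (multi-bracket pseudoknot layers,
`&` chain breaks). Paired regions become ideal double-helical stems
(rise 2.8 Å, twist 32.7°, C1′–C1′ 10.4 Å, N–N 3.0 Å — config constants
in the A-form neighborhood, not measurements); each stem is an
independent block in space and unpaired runs are smooth elevated arcs
between their anchors. The layout guarantees, by construction, that the
annotator recovers exactly the specified canonical pairs: within-stem
alternatives fail the nitrogen-distance or C1′ window, linker bases
carry 45°-tilted base planes (failing the coplanarity test against stem
bases), and linker–linker candidates in the C1′ window automatically
fail the 3.5 Å nitrogen cutoff because all linker nitrogen offsets are
parallel. This is verified over hundreds of random structures rather
than assumed.

Assemblies apply exact Cn/Dn operators (dihedral rings offset along the
axis), so generated symmetry is perfect at σ = 0. Perturbation modes:
per-atom Gaussian noise, rigid shuffles of a contiguous residue block,
and rigid misplacement of every chain after the first (degrading
interface metrics while leaving monomer accuracy intact). Synthetic
MSAs mutate a reference row i.i.d. with the per-site rate solved from
`(1−q)² + q²/3 = target identity`. Rosters assign each group a noise
level, participation rate, and up to 5 models per target with the first
model best; simulation of 6 groups with strictly ordered noise over 30
20-nt targets lets the full pipeline recover the true quality ordering
(Kendall τ = 1) in ≥ 95% of seeded runs — the problem sizes were chosen
as the smallest at which the ordering test is decisively powered.

What the generator does **not** emulate: real RNA backbone continuity
between stems (linkers are schematic arcs), all-atom base geometry and
hence realistic non-canonical pair diversity, base stacking, physically
folded tertiary contacts, or experimental artifacts (partial occupancy,
conformational heterogeneity). Passing tests therefore demonstrate the
correctness of the scoring and ranking machinery under controlled
degradation — not that the metrics have been validated against
experimentally determined structures.

## Missing-data policy (centralized)

Metrics that cannot be computed for a model are recorded as missing and
drop out of best-of reductions; a group with no scoreable model for a
target simply has no Z there (contributing 0 after flooring). Base-pair
F1 differs by convention: no submission is 0, dual absence of an
interaction type is null and leaves the mean. Exclusion lists remove
(group, target) cells before reduction and are logged. These rules are
implemented once, in the pipeline module.

## Limitations

- The geometric pair annotator is tuned for the coarse-grained residue
  model and idealized geometry; on experimental all-atom structures it
  is a rough screen, and ingesting annotations from a dedicated engine
  is the recommended path.
- Bit-exact parity with the reference binaries behind the published
  assessments (US-align, LGA, OpenStructure, AnAnaS) is a non-goal; the
  implementations follow the published conventions and are validated
  against internal brute-force oracles instead.
- Helical and cubic point groups are not detected (no such targets in
  scope), and symmetry detection presumes near-complete assemblies.
- The sequence-independent aligner preserves residue order; circular
  permutations and domain swaps are not found.
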