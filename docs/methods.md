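# Methods

## Problem and approach

`synortho` finds remote homologs of a seed gene across annotated viral
genomes when sequence similarity alone is too weak to be trusted, by
exploiting conserved gene order. The motivating system is the
*bv/odv-e26* (Bm8/Ac16/Ld127) family of alphabaculoviruses: a coiled-coil
protein whose homologs sit between two well-conserved anchor genes, *egt*
and *Bm9*, even when pairwise identity to the seed drops below 20%.

The pipeline has five stages:

1. **Anchor location.** Each genome's proteome is scanned with reference
   anchor proteins by exact Smith–Waterman alignment; the best hit is
   accepted if it reaches a score and reference-coverage threshold.
2. **Candidate extraction.** Genes strictly between the two anchors (the
   shorter arc on circular genomes) are the candidates. If Bm9 is missing,
   a symmetric window of genes around *egt* is used instead.
3. **RBH network.** Every candidate is searched against the full proteome
   of every other genome; an edge joins two genes when each is the other's
   best accepted hit (reciprocal best hit). The homolog family is the
   connected component containing the seed — connectivity, not cliques, so
   distant members can join through intermediates.
4. **Coiled-coil conservation.** Family members are scanned with a heptad
   register scorer, their coil fragments progressively aligned, and each
   alignment column classified by conservation (strict identity vs
   {I,L,V} equivalence, overall and per taxon group). Residue numbers are
   mapped between members through alignment columns.
5. **Phylogeny.** A neighbor-joining tree is built from alignment-identity
   distances, and agreement with a reference topology (e.g. a core-gene
   species tree) is quantified as the Robinson–Foulds distance.

## Pairwise alignment

Local (Smith–Waterman) and global (Needleman–Wunsch) alignment use the
Gotoh three-state recurrence with BLOSUM62. A gap of length L costs
`gap_open + gap_extend × L`. Defaults are 11/1 for the local search
engine (BLASTP convention) and 10/0.5 for the global identity calculation
(EMBOSS Needle convention). End gaps are penalized like internal gaps in
global mode. Percent identity follows the Needle convention — identical
columns over all columns including gaps — and an unknown residue (X)
scores 0 against everything and never counts as identical.

Determinism is part of the contract: traceback prefers diagonal over up
over left, and in local mode the optimum cell with the lexicographically
smallest end coordinate is used, so alignments are byte-reproducible.
The local aligner replaces a heuristic BLASTP search; over viral proteomes
of this size the exact optimum is affordable and strictly more sensitive,
and it removes an external binary from the workflow. No E-values are
computed — hit acceptance is by raw score (default ≥ 50) and coverage of
the shorter sequence (default ≥ 0.25), both config-exposed.

A batched score-only kernel (one query against a padded matrix of
subjects) drives the network search; it is exact, not heuristic, and is
checked against single alignments in the tests.

## Anchors and candidates

Anchor acceptance defaults: score ≥ 80 and coverage ≥ 0.5 of the
reference anchor. On circular genomes the candidate interval is the
shorter arc between the anchors (ties go to the forward arc); "downstream
of egt" when Bm9 is absent is operationalized as a symmetric window
(default 10 genes each side), because reading direction is ambiguous and
a symmetric window cannot miss the true neighbor. Genomes without an
*egt* hit are skipped with a logged warning. Candidate sets are invariant
under rotation of a circular genome's origin.

## Coiled-coil scanner

A coiled coil repeats seven residues (letters a–g) with hydrophobic
packing at positions a and d (the "1st and 4th"). The scanner slides a
window (default 21 residues) across the protein, scores all seven register
phases as the fraction of a/d positions occupied by a hydrophobic residue
(default set {I,L,V,M,F,A}), and accepts windows reaching a threshold
(default 0.7). Each covered residue adopts the phase with the largest
score-weighted support among accepted windows covering it; maximal
same-phase runs at least one window long become the reported intervals,
with the interval score recomputed as core hydrophobicity over the whole
interval. The score-weighted vote keeps a single boundary-straddling
window from splitting a consistently supported register — different
phases share one of their two residue classes mod 7, so boundary windows
can tie on raw score.

This is a deliberately transparent simplification of profile-based
predictors (COILS, Paircoil): it encodes exactly the heptad-hydrophobicity
criterion and nothing else, and all parameters are exposed. It finds
spurious short coils in random sequence at a rate consistent with the
threshold (a window of 6 core positions passes 0.7 by chance ≈ 1% per
phase); consumers that know the true domain should crop to it.

## Progressive alignment and conservation

Families are aligned progressively: pairwise global identities give
distances (d = 1 − identity), a UPGMA guide tree fixes the merge order
(ties broken by lexicographically smallest member id), and profiles are
merged by affine-gap profile–profile alignment with sum-of-pairs BLOSUM62
column scores ("once a gap, always a gap"). Gap penalties are scaled by
the product of profile depths so their weight tracks the sum-of-pairs
substitution scores. The result is independent of input order. This
aligner is adequate for families up to a few dozen members; iterative
refinement and consistency objectives are out of scope, and all
conservation statements are made against this aligner's output.

Conservation is evaluated per gap-free column (a gap vetoes conservation).
Equivalence classes are {I,L,V} — the branched/aliphatic substitutions the
family tolerates at coil core positions — plus a singleton class per other
residue, so strict identity always implies equivalence. The report
distinguishes columns whose residues all lie in the {I,L,V} class
(`in_equivalence_set`) from columns equivalent via identity alone, and
attaches per-taxon-group classes. Residue mapping between members goes
through shared columns and is bijective wherever neither row is gapped.

## Phylogeny

Neighbor joining uses the Saitou–Nei Q criterion with the standard
branch-length formulas, clamping negative lengths to zero; ties are broken
by the lexicographically smallest pair of cluster labels, so trees are
deterministic. Distances default to 1 − fractional identity with pairwise
deletion of gap columns; a Poisson correction (−ln(1 − p)) is optional.
NJ is exact on additive matrices, which the tests verify at 4–8 leaves.
Robinson–Foulds is computed over non-trivial bipartitions. Maximum
likelihood inference is out of scope: the claim being operationalized is
topological consistency with a reference tree, not likelihoods.

## Synthetic fixtures

The generator emulates the study conditions: small circular genomes of
single-exon CDS, an egt-like anchor (500 aa), a Bm9-like anchor (100 aa),
a 230-aa family protein carrying a 35-residue coiled coil (five heptads,
a/d positions constrained to {I,L,V}), and eight per-genome decoys
(80–250 aa), all descended from one ancestor proteome. Default divergence
is 0.3 substitutions/site on a star tree (≈50% pairwise identity between
family members — a deliberately hard but recoverable regime); an arbitrary
Newick generating tree is supported, with branch lengths multiplying the
divergence. Controlled deletions reproduce the real edge cases: genomes
missing Bm9 and a genome missing the family member.

Site classes make the ground truth exact: coil a/d positions draw from
{I,L,V}; other coil positions draw from the 17 residues outside {I,L,V},
so the planted core columns are exactly the all-{I,L,V} columns of any
family alignment and conservation recovery can be scored with precision
and recall of 1.0 rather than approximately. Substitutions are uniform
over the allowed alphabet minus the current residue, giving closed-form
expected identities ((1−t)² + t²/(k−1) per site for a k-letter class) that
the tests check against Monte-Carlo means. Evolution is indel-free by
default so ancestral residue numbering remains valid truth; a per-site
deletion rate exists for stress tests only. Output is byte-deterministic
per seed.

What the fixtures do **not** model: genome rearrangement, gene
duplication/loss other than the configured deletions, codon-level or
BLOSUM-weighted substitution, length variation within the family, and
compositional bias. Passing on fixtures therefore demonstrates the
pipeline's logic (anchoring, reciprocity, connectivity, register
bookkeeping), not its robustness to real annotation noise.

## Problem sizes and numerics

Test and acceptance runs use 4–10 genomes of ~11–14 genes, chosen to keep
the whole suite comfortably reproducible on a single CPU; the algorithms
themselves have no such limits. Brute-force alignment oracles enumerate
order-preserving matched-pair sets for sequences up to length 8. Floating
point comparisons in tracebacks use an absolute tolerance of 1e-9 against
integer-and-half-unit scores, so no accumulation issues arise at these
scales. Degenerate inputs (empty sequences, all-gap columns, asymmetric
distance matrices, missing seeds, contradictory generator configs) raise
typed errors rather than propagating bad values.

## Reproducing printed identities for the real proteins

The global aligner and residue mapper reproduce the published comparison
of the real family members — Bm8 vs Ac16 at 96.1% identity, Bm8 vs Ld127
at 17.3%, and the correspondence of Bm8 I96 to Ld127 V86 — when the
accessioned protein sequences (BmNPV T3, GenBank L33180.1; AcMNPV C6;
LdMNPV) are supplied as `tests/data/accessioned_e26_homologs.fasta` with
ids `Bm8`, `Ac16`, `Ld127`. The sequences are not redistributed with the
package, so those two acceptance tests fail with instructions until the
file is provided.
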