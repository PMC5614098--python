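# Methods

This note documents the models and procedures implemented in miniclust,
the parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical conventions that make every result
deterministic.

## Pairwise alignment

All similarity decisions rest on one affine-gap Smith–Waterman aligner
(BLOSUM62 by default; any NCBI-format matrix can be loaded). A gap of
length *k* costs `gap_open + k·gap_extend` with defaults (11, 1), the
standard pairing for BLOSUM62. From the optimal local alignment we report:

* **score** — the raw gap-penalised substitution score;
* **identity** — identical residue pairs / aligned residue-residue columns
  (gap columns excluded). Sequence identity has no single standard
  definition; this one is safe here because coverage is enforced as a
  separate criterion, so a short perfect match cannot masquerade as
  full-length similarity;
* **coverage** — aligned span length / sequence length, reported per
  sequence; "overlap of the shorter sequence" means the coverage of
  whichever sequence is shorter;
* **score per aligned residue** — score / aligned columns; used for member
  reassignment and the diversity filters. For a self-alignment it equals
  the mean diagonal matrix entry of the sequence.

Determinism: traceback ties resolve diagonal > gap-in-target >
gap-in-query, gaps close as early as possible, and the start cell is the
first maximal cell in row-major order. Because co-optimal alignments can
differ in identity, alignments are additionally computed in a canonical
orientation (the sequence with the smaller (residues, accession) pair acts
as the DP query, fields swapped back afterwards), which makes identity and
coverages exactly symmetric under argument exchange. The DP kernel is
numba-compiled; a pure-Python quadratic-space implementation of the same
conventions serves as the test oracle.

Sequences with zero positive-scoring local alignment get identity and
coverage 0 and score-per-residue −∞, so they can never win a
"most similar" comparison.

## Redundancy filter

The five-letter reduction partitions the alphabet into
{A,S,T,G,P | C | D,E,N,Q,B,Z,X | K,R,H | M,I,L,V,F,Y,W} — tiny/polar,
cysteine, acidic/amide, basic, hydrophobic. Any fixed five-class partition
would do: the hash (64-bit blake2b of the reduced string) only proposes
candidates, and every merge is verified by exact full-alphabet column
identity at equal length. A 64-bit digest makes accidental collisions
negligible at desk scale (and harmless in any case).

## Fragment absorption

A cluster is absorbed into another when its representative aligns to the
target representative with identity ≥ 0.90 over ≥ 0.95 of its own length,
regardless of significance. Two implementation decisions beyond the rule
itself:

* absorption targets must have an equal-or-longer representative, clusters
  are processed shortest-first, and the best-scoring eligible target wins
  (ties: longer target, then smaller accession);
* every *other* member of an absorbed cluster is verified against the new
  representative as well (it must meet the level thresholds or the
  fragment rule itself). Without this, chains of absorptions can leave a
  member attached to a representative it was never compared against,
  silently violating the membership guarantees. At desk scale the extra
  alignments are cheap; the resulting invariant — every member/
  representative pair satisfies its level's thresholds or the fragment
  rule — is checked exhaustively in the tests.

The rule is applied after both the hash step and the greedy 90% step.

## Greedy incremental clustering (90% level)

Sequences are processed longest-first (ties: lexicographic accession) and
join the best-scoring existing representative satisfying identity ≥ 0.90
and ≥ 0.90 coverage of the shorter sequence, else found a new cluster.
Assigning to the *best* eligible representative (rather than the first
found) costs one scan over representatives but is order-independent and
gives more compact clusters. Representatives are the longest member of
their cluster by construction.

## Set cover with reassignment (50% and 30% levels)

Both deeper levels are built directly from the 90%-level representatives,
not from each other. The acceptance graph has an edge when identity meets
the level threshold (0.5 / 0.3) and *both* coverages are ≥ 0.8 — the
bidirectional reading of "80% sequence length overlap", consistent with
how reference-cluster resources state the criterion. Greedy set cover
repeatedly selects the uncovered vertex covering the most uncovered
vertices (ties: longer sequence, then smaller accession); its cluster is
itself plus its uncovered neighbours. A single reassignment pass then
moves each non-representative member to the representative with the
maximal score per aligned residue among those still meeting the edge
criterion. Edges use identity+coverage as stated; reassignment uses
score-per-residue as the similarity — the two criteria are deliberately
kept distinct. Coarser-level membership is expanded through the finer
level, so every 30%-level cluster is a union of whole 90%-level clusters;
expanded (non-representative) members inherit membership transitively and
are not re-checked against the coarse representative.

## Incremental updates

Updating to a new sequence set preserves identifiers: deprecated members
are dropped (a cluster whose representative vanished promotes its longest
remaining member, keeping its ID); genuinely new sequences are compared
against surviving representatives only — linear in the number of new
sequences — and join the best eligible one; leftovers are clustered among
themselves by set cover and numbered after the existing maximum. An
accession whose residues changed is a hard error: accessions are
immutable. The alignment-call counter in the align module exists to make
the linearity claim testable. Release tags must strictly increase; the
pipeline reuses the alignment files of clusters whose membership did not
change.

## Cluster MSAs, consensus, profiles

Cluster alignments are center-star around the representative: each member
is aligned pairwise to the representative, representative positions define
the match columns, member residues opposite representative gaps (and
unaligned member flanks) become lowercase insertions — A3M semantics
directly, with member coordinates fully recoverable from each row. A
general progressive aligner is unnecessary here because every member
already satisfies identity and coverage thresholds to its representative;
the center-star construction is deterministic and linear in cluster size.

Profiles and consensus use uniqueness weighting (duplicate rows collapse),
so repeating a sequence cannot bias a column. The consensus residue
maximises observed counts blended with a uniform pseudocount (total weight
1.0, configurable); ties prefer the residue with the higher matrix
self-score, then alphabetical order. Column scores of the PSSM are the
frequency-weighted average of the substitution-matrix rows of the observed
residues — finite for unobserved residues by construction, and exactly the
sequence's own matrix rows for a single-sequence alignment.

Consensus headers carry the cluster ID, representative accession, cluster
size, up to five non-redundant member descriptions — reviewed entries
outrank unreviewed ones, descriptions containing hypothetical / unknown /
uncharacterized / putative rank last, remaining ties resolve by frequency
then lexicographically — and all member accessions.

## Boosted alignments

A cluster profile is searched against the database of cluster consensus
sequences by local profile-sequence DP; hits are scored with the
Karlin–Altschul E-value `K·m·n·exp(−λS)` using the gapped-BLOSUM62
constants (K, λ) = (0.041, 0.267) and accepted below 1e-3 (both
configurable; the enrichment-search threshold is not standardised
anywhere, so it is exposed). Hits are merged into the alignment by
aligning them to the consensus, the profile is rebuilt, and the search
iterates (default 4 rounds) without ever dropping a previous hit, so the
hit set grows monotonically. The enriched alignment is filtered at
score-per-aligned-residue thresholds 0.0 / 0.5 / 1.1 against the
consensus — heuristically ~10/20/30% sequence identity — scoring match
columns only (insertions are unscored); the first record is always kept.
Filtering is idempotent and nested across thresholds.

## Annotation transfer

Acceptance is per database (Pfam/SCOP/PDB are never pooled): matches are
processed by increasing E-value (ties: longer span, then target ID) and
accepted when E < 0.01 and the overlap with already-annotated regions is
< 10% of the candidate's own query span. Transfer evaluates, for each
member and accepted annotation, the member-vs-consensus substitution score
over the annotated match columns (read off the alignment; members with no
residue in the span are skipped) and emits the annotation iff

    E_subali = E_domain + K · L_consensus · exp(−λ · s_subali) < 0.01.

The exponent is implemented as −λ·s: the term is an E-value of the
subalignment, so it must *vanish* for high-scoring (clearly homologous)
subalignments and blow up for poor ones. With a positive exponent the test
would reject exactly the members it is meant to accept. A
`literal_formula` switch with the positive sign is provided for auditing.
E_subali is strictly decreasing in the subalignment score, increasing in
E_domain and consensus length, and never below E_domain. Transferred
coordinates are mapped through the alignment onto the member (1-based
inclusive in all TSVs; internal code is 0-based half-open).

## Consistency evaluation

GO similarity between terms is the information-content ratio
`2·log P(LCA) / (log P(a) + log P(b))`, with P the probability that a
protein is annotated with the term or any descendant. The ontology is a
DAG, so the "last common ancestor" is taken as the common ancestor with
minimal P (maximal information content; ties on term ID) — the standard
resolution when a tree is assumed but a DAG is supplied. The logarithm
base cancels; natural log is used. Term probabilities can be supplied or
estimated from an annotation corpus with ancestor propagation (unobserved
terms get half the smallest observable frequency to keep logs finite;
roots are forced to 1). Set similarity is the best-match average in both
directions; keyword similarity is the Dice coefficient (after dropping the
technical-term and coding-sequence-diversity categories when a category
map is available); name similarity is 1 − Levenshtein/max-length on
normalised names (case-folded, the word "protein" removed, names starting
with uncharacterized/putative/potential/probable/inactive/likely/unknown
excluded).

Per cluster we report the worst and mean score between the representative
and every other member, per type, plus the cross-type average; pairs with
undefined scores (missing annotations) are *skipped*, not scored zero —
zero-scoring would conflate missing data with inconsistency. Cluster-level
averages aggregate over clusters where the type is defined. Compactness is
the mean and minimum all-pairs identity, down-sampling to 10 members
(seeded) for larger clusters.

## Synthetic data

Families are grown from independent uniform-random founder sequences;
members are mutated to an exact target identity (positions chosen without
replacement, replacements drawn by BLOSUM62 exchangeability, never the
original residue) and optionally truncated to a 30–60% prefix or suffix to
exercise the fragment rule. The first member of each family is the
unmutated founder: it is the natural representative (longest member,
smallest accession) and makes member-to-representative identity equal the
requested within-family identity exactly. Mutating every member
independently would instead make member–member identity ≈ identity², so a
"95% family" would straddle the 90% threshold and the planted partition
would be unrecoverable in principle, not just in practice. A hierarchical
variant diverges subfamily founders to ~0.70 identity from a shared
ancestor (sibling founders then share ~0.5), so 30%-level clustering
merges subfamilies that 90%-level clustering keeps apart.

The annotation generator builds a balanced term tree (probabilities
decreasing geometrically with depth), assigns each family a leaf term, a
three-keyword set and a name, and perturbs each protein independently with
a given noise probability (sibling-leaf swap, keyword drop+add, name
typo).

What this emulates — and what it does not: substitutions are i.i.d. across
positions with no indels within families (indels enter only via
fragments), the residue background is uniform rather than empirical, and
annotations are noiseless labels of a planted truth rather than the
correlated, propagation-biased annotations of real databases. Passing
tests therefore demonstrate the correctness of thresholds, graph
algorithms, bookkeeping and formulas — not retrieval performance on real
protein families, where domain architecture, repeats and biased
composition matter.

## Problem sizes and determinism

The default test corpora use 3–20 families of 3–6 members at sequence
length 30–200, and 10–20 seeded replicates per stochastic check; the
acceptance script uses 10 replicate fixtures for recovery and one
8-family corpus for the database-level statistics. These sizes keep the
full all-vs-all stages comfortable on one core while leaving every rule
(fragments, reassignment, boosting, transfer) exercised. All generators,
clustering steps and the pipeline are pure functions of their seeds and
inputs; rebuilding a release from the same input is byte-identical. The
all-vs-all stages are O(n²) and log a warning above 2000 sequences —
scaling to millions of sequences (prefiltering, k-mer indexing,
parallelism) is explicitly out of scope.
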