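# Methods

## Motif model

Each of the four CYP motifs is compiled from PROSITE-style pattern text into
per-position residue sets.  A subset of positions are *anchors* — the
residues conserved across the superfamily — and only anchors are scored; the
remaining positions inform strictness but not match quality.  Defaults:

| motif   | pattern               | anchors (1-based)  | mandatory | min score |
|---------|-----------------------|--------------------|-----------|-----------|
| ihelix  | `[AG]G-x-[DE]T[TS]`   | 1,2,4,5,6          | —         | 3 of 5    |
| khelix  | `E-x-x-R`             | 1,4                | 1,4       | 2 of 2    |
| meander | `FDPER`               | 1,3,5 (F, P, R)    | —         | 2 of 3    |
| heme    | `F-x-x-G-x-R-x-C-x-G` | 1,4,6,8,10         | 8 (C)     | 4 of 5    |

The K-helix glutamate/arginine pair and the heme-loop cysteine (the heme
thiolate ligand) are mandatory: no window failing them is ever reported.
The minima are the loosest values that detect the naturally occurring motif
variants in curated CYPomes while keeping random 20-letter background below
the reporting threshold; they are configurable per `MotifConfig`.  An
unknown residue `X` satisfies wildcard positions only — it never fabricates
anchor evidence.

Survey tables of real CYPomes print a handful of motif strings that fall
below these minima (a degenerate `AGSTSL` I-helix, a `FPDPE` meander); the
engine deliberately reports those motifs absent rather than lowering the
minima, which would flood random background with false K-helix- and
meander-sized hits.  The shipped fixtures keep such strings verbatim and the
acceptance suite asserts the absent call for them.

### Heme-loop indel tolerance

CYP20-family proteins carry a single-residue indel in the heme loop.  When
enabled (default), windows one residue shorter or longer than the pattern
are evaluated under the best single gap placement (exhaustive over gap
positions) and flagged `indel_variant`.  A variant is reported only when no
exact-length match at an adjacent start (±1) scores at least as well;
otherwise the "variant" is just a shifted re-reading of an ordinary site.
Without this rule, every ordinary heme site would also produce an
equal-scoring insertion reading one position to its left, which would then
win leftmost tie-breaks.

### Chaining

`chain_motifs` selects at most one match per motif maximizing total anchor
score subject to canonical order and start-to-start spacing bounds:
ihelix→khelix ∈ [38, 75], khelix→meander ∈ [40, 65], meander→heme ∈
[18, 35] (the envelope of spacings in curated cnidarian CYPomes plus a
margin; configurable).  When an intermediate motif is absent — e.g. the
degenerate CYP20 I-helix — the flanking pair is constrained by the interval
sum of the skipped steps, so partial chains remain spacing-checked.  Ties
break to the leftmost I-helix start, then K-helix, and so on (absent sorts
last), making the chain total and deterministic.  The DP is exact: the test
suite checks it against exhaustive enumeration over all ordered window
subsets on sequences up to 100 residues.

## Status classification

Evaluated in order complete → partial → fragment → non_cyp:

* **complete** — all mandatory motifs present and ordered, length within
  [440, 650] residues, start and stop evidence `yes`, and no explicit
  HMM-mismatch flag.  The window is wider than the nominal ~500 because
  genuine complete genes in curated CYPomes range roughly 440–525.
* **partial** — motifs complete but ≥1 completeness condition fails;
  `reasons` lists every failure.  Unknown start/stop evidence counts as a
  failure (conservative: partial, not complete).
* **fragment** — ≥1 motif detected but not all mandatory ones.
* **non_cyp** — no motif at all.

The I-helix is excluded from the mandatory set by default because the CYP20
lineage lacks it yet is a real CYP family.  External HMM evidence is an
ingested boolean (`hmm_match` header token or evidence TSV), never computed;
an explicit `False` blocks a complete call, and absent evidence changes
nothing.

## Nomenclature

Identity is `100 × identical pairs / mutually aligned (both non-gap)
columns` of a global Needleman–Wunsch alignment (BLOSUM62, gap open 10,
extend 0.5), with coverage = aligned columns / shorter raw length.  Pairs
with coverage < 0.5 are unreliable and never merge groups — this stops short
fragments from inflating identity.  Both thresholds are strict: exactly
40.0% is *not* same-family, exactly 55.0% not same-subfamily.

Families and subfamilies are single-linkage components (the transitive
reading of "belong to the same family"); a warning is emitted when chaining
joins a pair below the threshold.  Queries anchor to the family of their
highest-identity named reference above threshold (ties to the
lexicographically smallest family label); the rest cluster de novo into
novel families numbered from a configurable sentinel (9001 by default —
official registry numbers are committee-assigned and not computable).
Subfamily letters run A…Z, AA, AB… in order of smallest member id, skipping
letters already used by named references in that family; gene numbers run
1..n by member id.  All labels are canonical under input permutation.

## Phylogenetics and clan assignment

Tree inference here is a desk-scale stand-in: neighbor joining (Saitou–Nei
Q-criterion) on Kimura-corrected protein distances
`d = −ln(1 − p − 0.2 p²)` with saturated pairs capped at 5.0.  Ties in Q
break to the smallest (row, column) label pair; negative branch lengths are
clamped to zero with the deficit moved to the sister branch.  NJ recovers
the generating topology exactly on additive matrices (tested for 4–8 taxa,
and cross-checked against scikit-bio's NJ).  External ML trees are ingested
as first-class Newick input — the clan logic, not the tree engine, is the
procedure of interest.

Alignment columns with gap fraction > 0.5 are trimmed before distances.
Bootstraps resample columns with replacement (seeded); support is the
percentage of replicate NJ trees containing each original bipartition.
Rooting places a degree-2 root at the midpoint of the edge separating the
outgroup; a non-monophyletic outgroup roots on the edge maximizing the
outgroup fraction, with a warning.  Rooting preserves all leaf-to-leaf path
lengths.

Clan assignment walks from each query leaf toward the root and stops at the
smallest clade that contains references: if they share one clan and the
clade's support is ≥ 50, that clan is assigned; clades below 50 support are
skipped (not treated as evidence); if the references span multiple clans
before any qualifying clade, the query is `unplaced` — mirroring how deep
unsupported branches are discounted in published CYP phylogenies.  Trees
without any support annotation are treated as fully supported, with a
warning, so ingested trees lacking bootstraps remain usable.

## Synthetic data

The generator emulates what the pipeline assumes about real CYPomes:
~500-residue proteins with the four motifs at table-derived spacings,
family structure at controlled identity, clan-level divergence, and
truncation-derived partials/fragments.  Construction:

* **Clans** descend from independent random ancestors (not mutation
  chains), guaranteeing between-clan separability for NJ.
* **Families** are founder copies mutated at a rate targeting ~25% pairwise
  identity between families; **genes** are founder copies mutated toward
  ~65% within-family identity.  Rates come from inverting
  `identity ≈ q² + (1 − q²)/20`; since anchors are held fixed, achieved
  identities are *measured* (Hamming, valid because mutation is
  substitution-only) and reported in `achieved_stats` rather than assumed.
  Defaults: 4 clans × 3 families × 4 genes (48 genes), 15% partials, 15%
  fragments, 10 decoys, length 500.
* **Degradation**: partials lose an N- or C-terminus outside the
  motif-spanning core (start or stop evidence lost, motifs intact);
  fragments lose a terminus covering a mandatory motif.  Truncation never
  creates new windows, so truth stays valid.
* **Scrubbing**: every emitted sequence (and every decoy) is scrubbed of
  background windows that would qualify as motif matches, by seeded
  mutation of window anchors to "quiet" residues with a verify-and-keep
  loop.  This is what makes status recovery *exact by construction* — the
  chain can only find the planted signal.  Real proteomes are of course not
  scrubbed: passing recovery tests shows the decision rules are implemented
  correctly, not that detection is error-free on diverged real sequences.
* All randomness flows from the single spec seed; runs are bit-for-bit
  reproducible.

The generator does not emulate codon-level gene models, introns,
empirical substitution matrices, or indel evolution outside the heme loop —
alignment inference on real data is correspondingly harder than on the
gap-free synthetic cohorts.

## Shipped fixtures

Three TSVs transcribe the published motif-occurrence surveys of the brown
hydra, stony coral and moon jellyfish CYPomes (84 gene rows: positions,
matched strings, lengths), and one TSV carries the published per-species
complete/partial/fragment tallies.  One survey row is omitted because its
printed heme position exceeds its printed protein length, and two rows print
colliding coordinates for adjacent motifs; the planting utility plants
motifs in canonical order and skips a colliding placement, and tests assert
the resulting behavior.  Fixture coordinates are 1-based inclusive, with
`-`/`–` as the absent marker.

## Problem sizes and tolerances

The default test and acceptance runs use: 84 survey rows (~330 motif
placements), 200+ random chaining cases ≤100 aa against exhaustive
enumeration, 4–8-taxon additive NJ recoveries, and one default synthetic
cohort (48 genes + 10 decoys; ~1,000 global alignments for naming; 100
bootstrap replicates over a 46-taxon alignment).  Identity calibration is
asserted at ±5 percentage points of target over ≥20 pairs; clan accuracy at
≥95%; family recovery at ARI = 1.0; status recovery exact.

## Known limitations

* Anchor minima and spacing bounds are a reconstruction of curation
  practice, not a published algorithm; genuinely degenerate motifs below
  the minima are reported absent by design.
* Single-linkage naming can chain families through intermediate sequences;
  the warning surfaces it but the merge stands, as the transitive reading
  of the nomenclature rule dictates.
* NJ on non-additive distance matrices is a heuristic; for publication-grade
  clan calls, ingest an ML tree and use the clan walk on it.
* The clan walk reconstructs by rule what curators do by inspecting clades;
  on trees with pervasive low support it returns `unplaced` rather than
  guessing.
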