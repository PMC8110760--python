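# cypome

Annotation toolkit for the cytochrome P450 (CYP) superfamily: motif-based
candidate verification, curation-status classification, percent-identity
nomenclature, and phylogenetic clan assignment, with per-species CYPome
composition reports.

## The problem

Cytochrome P450s are heme-thiolate monooxygenases found across all domains of
life; a genome's full CYP complement (its *CYPome*) underlies chemical
defense, fatty-acid metabolism and steroidogenesis.  Annotating a CYPome from
genome-derived protein candidates involves a standard chain of decisions that
this package makes reproducible:

1. **Motif verification.**  Real CYPs carry four short conserved motifs in a
   fixed order — the I-helix `[AG]G-x-[DE]T[TS]`, the K-helix `E-x-x-R`, the
   meander coil `FDPER`, and the heme loop `F-x-x-G-x-R-x-C-x-G`, whose
   cysteine is the axial heme ligand.  `cypome` scans candidates with
   anchor-scored degenerate patterns (the conserved residues count; the
   variable ones do not), tolerates the single-residue heme-loop indel seen
   in CYP20-family proteins, and chains the best hits under canonical order
   and spacing constraints by dynamic programming.
2. **Status classification.**  Candidates become `complete` (full length,
   start/stop evidence, all mandatory motifs), `partial` (motif-complete but
   truncated — presumed functional), `fragment` (missing mandatory motifs),
   or `non_cyp` (no motifs).
3. **Nomenclature.**  CYP names encode identity tiers: genes with >40%
   amino-acid identity share a family (number), >55% a subfamily (letter),
   e.g. CYP17A1 = family 17, subfamily A, gene 1.  Both thresholds are
   strict.  Identity comes from global Needleman–Wunsch alignments
   (BLOSUM62) over mutually aligned columns with a coverage gate; families
   are single-linkage components, anchored to named references when
   possible, otherwise minted as novel families.
4. **Clan assignment.**  CYP families group into *clans* — families that
   repeatedly form one clade in metazoan phylogenies.  `cypome` builds
   neighbor-joining trees on Kimura-corrected protein distances (or ingests
   an external ML tree in Newick), roots them on an outgroup family,
   attaches bootstrap supports, and assigns each query to the smallest
   supported clade containing clan-labeled references — or reports it
   unplaced.
5. **Reporting.**  Per-species status tallies, clan counts/proportions over
   the functional (complete + partial) genes, and a three-state clan
   presence matrix (present in genes / fragment evidence only / absent).

A seeded synthetic-CYPome generator with known truth (planted motifs,
families at controlled identity, clan-structured divergence,
truncation-derived partials/fragments, motif-free decoys) makes every stage
testable without downloads.  The package also ships motif-survey tables for
three cnidarian CYPomes (brown hydra, stony coral, moon jellyfish) as
worked-example fixtures.

## Worked example

```sh
# generate a synthetic CYPome (2 clans x 2 families x 3 genes + decoys)
cypome --seed 5 simulate --out-dir sim --n-clans 2 --families-per-clan 2 \
       --genes-per-family 3

# classify candidates
cypome classify sim/cypome.fasta -o cls.tsv

# NJ tree with bootstraps, rooted on the generated outgroup
cypome --seed 3 tree sim/aligned.fasta --reps 20 --outgroup REF_outgroup -o tree.nwk

# clan assignment against the clan-labeled references
cypome clans tree.nwk sim/reference_clans.tsv -o clans.tsv
```

The classification table starts:

```
id          species    length  status    reasons                     ihelix_pos  khelix_pos  meander_pos  heme_pos
syn_c1f1g1  synthetic  500     complete                              226         289         349          367
syn_c1f1g2  synthetic  327     partial   short_length;missing_start  53          116         176          194
```

`syn_c1f1g1` is a full-length gene with the four motifs at canonical
spacings; `syn_c1f1g2` lost its N-terminus (start codon gone, 327 of 500
residues left) but keeps every motif — a partial gene, presumed functional.
The clan table then places each query inside its reference clade, e.g.
`syn_c1f1g3  clan 2  100.0  6`: the smallest supported clade containing a
reference holds 6 leaves, all references in it are clan 2, bootstrap 100.

Summaries reproduce published curation arithmetic.  Feeding the shipped
per-species curation tallies through the report:

```sh
cypome report src/cypome/data/results_counts.tsv --json
```

prints for the brown hydra `"complete": 19, "partial": 5, "fragment": 11`
and `"minimum_functional": 24` — 19 complete plus 5 partial genes give a
minimum of 24 functional CYPs in that genome.

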