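# Methods

This note documents the models, conventions and numerical choices behind
mitocomp, and what the synthetic-data generator does and does not
emulate.

## Coordinate and orientation conventions

Internal coordinates are zero-based, half-open, on the majority (J)
strand as deposited; printed reports and feature tables convert to
1-based inclusive (the GenBank dialect).  A feature that wraps the
origin of a circular molecule is stored as an ordered pair of spans —
never by rotating the sequence — so deposited coordinates survive a
read/write round trip.  N-strand features are returned
reverse-complemented ("coding orientation") by `extract_region`.
Gene names are normalized through a packaged, editable synonym table
(`data/gene_synonyms.tsv`); Leu/Ser tRNAs carry isoacceptor suffixes,
resolved through the anticodon when a record annotates only "tRNA-Leu".
A record lacking a control-region feature gets the gap between srRNA and
tRNA-Ile (the ancestral position) labeled as the control region with an
`inferred` provenance flag.

## Composition statistics

Skews follow the standard definitions AT-skew = (A − T)/(A + T) and
GC-skew = (G − C)/(G + C); a zero denominator flags the skew undefined
rather than zero.  Ambiguity codes are excluded from counts.
Whole-genome values are computed on the J-strand; per-gene and
codon-position values in coding orientation.  Presentation rounding is
1 decimal for percentages and 3 for skews; computation is always full
precision.  Start codons are reported literally (ATN, TTG, GTG and TCG
all occur as legitimate mitochondrial starts); a CDS length not
divisible by three is legal only when the remainder is `T` or `TA`, the
incomplete stops completed to UAA by polyadenylation — anything else
raises an annotation-inconsistency error naming the gene.  RSCU uses the
invertebrate mitochondrial code (NCBI table 5), excludes stop codons,
and by construction averages to 1 within every synonymous family with
nonzero total.

## Spacer consensus

The consensus is a *presence-set* consensus, not a frequency-threshold
one: each column's set of distinct observed residues maps to its IUPAC
ambiguity letter, so a single deviant taxon is enough to turn an A
column into W.  This is deliberate — the conserved-spacer motifs the
method targets encode any observed residue.  Columns that are gap in at
least half the rows are trimmed, which confines lineage-specific
terminal extensions to per-genome listings and reports the conserved
core.

Alignment of a spacer panel is anchored by extraction: the spacer is the
literal sequence between two annotated genes, so equal-length panels are
positionally homologous and are kept as-is.  These stretches are AT-rich
and of very low complexity; similarity scoring on them can always find a
"better" shifted alignment by chance, so re-aligning equal-length panels
would only destroy the anchoring (we verified this under several scoring
schemes).  When lengths differ, sequences are added progressively
against the running profile with frequency-weighted column scores
(2·f − 1 ∈ [−1, +1], i.e. match +1 / mismatch −1 against a single row),
internal gap −4 and terminal gap −2, ties broken toward the most matched
columns and then deterministically.  The stiff internal gap cost (twice
the full match↔mismatch swing) prevents spurious micro-shuffles on
low-complexity sequence; the half-price terminal gaps let
lineage-specific flanking residues hang out of the profile without
letting a row shed a deviant terminal residue for free.  One genuine
ambiguity remains: a single extra A adjacent to a terminal A/C column
cannot be assigned to core or extension on sequence evidence alone.

## tRNA stems and the five substitution patterns

Cloverleaf stems are *positional*: the arm-boundary table fixes expected
stem extents, and pair k couples the k-th base of the 5′ strand with the
k-th base (outside-in) of the 3′ strand whether or not the structure
prediction drew that bond.  Unpaired stem positions thus remain mismatch
candidates, matching how mismatches are reported in practice.  Canonical
pairs are Watson–Crick plus G–U (required for G–U → A–U to be a
hemi-cbc).  The classification of an undirected change between two
pairs: equal → identity; both canonical with one base changed →
hemi-cbc; both canonical, both bases changed and reversed → mbc (checked
before cbc, since the mirrored intermediate state is non-canonical);
both canonical otherwise → cbc; exactly one canonical → rbc; neither →
nrbc.  Pairwise comparison cannot recover the direction of a reparative
change, so rbc covers canonical↔non-canonical in either direction and
the report annotates which taxon holds the canonical state.  Stems of
unequal depth are compared over the shared depth, the surplus reported
separately — never force-aligned.

## Conservation profiling

A column counts as identical only when every row carries the same
unambiguous nucleotide; gaps and ambiguity codes make a column variable,
and gap-containing columns stay in the denominator (this reproduces the
974/1350 → 72.1% style of arithmetic exactly).  An alternative
denominator excluding gap-only columns is reported alongside.  The
%INUC–A+T association is a plain Pearson correlation; with ~22 gene
profiles a single panel estimates it with a standard error around 0.2,
so tests of the generator-imposed correlation average over replicate
panels.  Group summaries flag groups represented by fewer than two
genomes.

## Control-region elements

All detectors are exact (no mismatches).  Homopolymer and (TA)n finders
report maximal runs (defaults: minimum 10 nt runs, 3 TA units).  Macro
repeats are maximal exact repeated substrings (length ≥ 30 by default)
with at least two non-overlapping copies separated by ≥ 1 nt; abutting
copies are a different phenomenon (tandem arrays) and are listed
separately; repeats whose every copy lies inside a longer reported
repeat's copies are suppressed.  Candidates come from per-shift maximal
match runs (every maximal repeat is witnessed by some occurrence pair
with mismatching flanks), which is O(n²) in the sequence length — ample
for control regions of a few kb, and verified against an all-substring
brute-force oracle in the tests.  Stem-loops are perfect inverted
repeats (Watson–Crick + G·U), default stem ≥ 6 bp and loop 3–20 nt,
maximal in the sense that the stem can be extended neither outward nor
inward within the loop constraint; results are ranked by stem length and
then 3′-proximity, and two optional flank-motif checks (5′ `TATA`,
3′ `G(A)nT`) are reported per hairpin.  The whole-region report treats a
hairpin contained inside another element (a (TA)n stretch and a macro
repeat both fold readily) as part of that element, not as a separate
conserved stem-loop.

## Supermatrix assembly

Gene blocks are aligned columns over a shared taxon set; taxa missing
from a block become all-gap rows.  The four datasets follow the standard
recipe: P123 = 13 PCG blocks, P123R adds 2 rRNA and (by default) 19 tRNA
blocks (tRNA-Ile, -Gln, -Met excluded as not universally available),
P12/P12R exclude third codon positions.  Dataset assembly tracks each
PCG column's true codon phase, so the P12 partitions are the two
surviving codon-position classes per gene — stride-2 ranges — giving the
26/39/47/60 partition counts for a full complement.  The standalone
`exclude_third_positions` operation instead recomputes phases naively
from the block frame after removal, and is therefore documented as
non-idempotent.  Partitions are emitted in the stride dialect shared by
RAxML and PartitionFinder (`start-end\3`), with ranges running to the
block end as is conventional.  Matrices round-trip through relaxed
PHYLIP and NEXUS (with a sets block).

## The synthetic-data generator

The generator emulates the *structure* of a fly mt genome, not its
evolution: there is no tree, no substitution model, and no rate
heterogeneity.  What it reproduces, and why:

- **Gene complement and order** — the packaged ancestral insect
  arrangement (23 J / 14 N), with typical gene lengths; editable as data
  (`data/gene_order.tsv`).
- **Protein-coding genes** — codon-wise sampling from position-specific
  base frequencies (defaults: A+T 68/66/90% at positions 1/2/3 with the
  empirically observed position skews), canonical starts, complete
  (TAA/TAG) or incomplete (`T`) stops per the order table.  In-frame
  stops are repaired by redrawing only the third base over the legal
  {C, T}, which leaves the position-3 A+T target essentially unbiased.
- **tRNAs** — instantiated from 22 packaged all-canonical cloverleaf
  templates (AT-biased stems and loops; tRNA-Ser(AGN) lacks the DHU
  arm), with configurable planted stem mismatches; genomes carry a U–U
  pair in the tRNA-Arg acceptor stem and the tRNA-Val TΨC stem by
  default.
- **Spacers** — realizations of the three conserved motifs planted
  between their flanking genes in the correct orientation (the
  tRNA-His–ND5 spacer reads on the N strand).
- **Control region** — poly-T (15 nt), (TA)₈, poly-A (13 nt), a 3′
  stem-loop (stem 10, loop 6) and two non-tandem macro repeats (72 and
  36 nt) planted at recorded coordinates with guard bases that make each
  element exactly maximal; accidental background hairpins are scrubbed
  so the structural report reflects only what was planted.
- **Whole-genome composition** — after all fixed parts are drawn, the
  rRNA background is constructed as an exact base multiset solving the
  genome-wide A+T and AT-skew targets, so realized A+T lands within
  about one percentage point of the target and the length is exact.
  The feasible A+T envelope is roughly 0.70–0.79 under the default gene
  complement; targets outside it raise before emission, as do skew
  targets the remaining pool cannot absorb.  The GC-skew target is
  optional (default uncontrolled).
- **Panels** — per-gene alignments realize an exact number of identical
  columns (so %INUC assertions are exact), with per-gene
  conservation/composition targets drawn from a bivariate normal with a
  configurable correlation; spacer panels realize each motif column as a
  majority residue plus one deviant row per alternative residue, the way
  clade panels that motivate IUPAC motifs actually look.

Everything planted is recorded in a truth sidecar whose coordinates are
valid against the emitted genome; the same seed yields byte-identical
artifacts.  Because the generator plants structure rather than evolving
sequences, passing tests demonstrate that the detectors and statistics
recover *known* structure exactly under realistic composition — they do
not demonstrate robustness to alignment error, annotation noise,
heteroplasmy or genuinely ambiguous element boundaries in real records.

## Problem sizes and defaults used in tests

Test genomes are full-size (~16.3 kb) since generation is fast; oracle
comparisons for the repeat and stem-loop finders use seeded random
sequences of 0.3–2 kb, where the brute-force oracles remain exact and
quick.  Acceptance checks embed the two reported macro-repeat sequences
(72 and 36 nt) in a 1.5 kb seeded background with copies 300 nt apart
and distinct flanking characters, so each planted repeat is exactly
maximal.
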