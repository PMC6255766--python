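# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Coordinates and the circular genome model

All coordinates are 1-based and inclusive, matching published mitogenome
gene tables. A feature that spans the replication origin is stored as an
ordered pair of segments (e.g. the control region as `(15565, 16796),
(1, 58)`); no feature ever has `end < start`. Feature lengths are always
computed from coordinates. When a source table also prints a size and it
disagrees with the coordinates, the coordinate value wins and a warning is
emitted: in the bundled turtle table this happens once (nad3, printed 348
vs coordinate-derived 349), and only the coordinate value closes the
circular coverage identity 16,685 + 124 − 13 = 16,796 exactly.

Adjacency gaps are `start(next) − end(prev) − 1` on the linearized circle,
with one record per adjacent pair including the junction back to the first
feature. Positive gaps are spacers, negative are overlaps, zero is neither;
this makes `Σ lengths + Σ spacers − Σ overlaps = genome length` an exact
invariant, which the test suite checks on both the bundled table and
generated genomes.

## Start/stop codon classification

With a sequence present, a protein-coding gene's start codon is its first
oriented 3 nt and the stop field is its trailing `length mod 3` nt (3 when
divisible). Classification: a complete stop of the vertebrate mitochondrial
code (TAA/TAG/AGA/AGG), an incomplete T or TA stop (completed to TAA by
polyadenylation in vivo), or a "trailing"/"noncanonical" label for anything
else. Annotated codons from a source table are carried verbatim alongside
the frame-derived values with an agreement flag — printed tables sometimes
list single-base stops for genes whose length is divisible by three, and
the package reports the discrepancy rather than guessing intent.

## Composition conventions

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C). Partition pooling follows
comparative-mitogenomics practice: protein-coding genes are pooled 5'→3'
with light-strand genes reverse-complemented; tRNA and rRNA genes are
pooled in the native heavy-strand register; the control region as
annotated. Feature sequences are pooled as extracted, so bases inside gene
overlaps count once per covering feature (the alternative — deduplicating
overlap bases — changes pooled totals by ≤13 bp here and is not used).
Ambiguous bases are excluded from skew denominators and from A+T%.
Percentages are reported to two decimals.

## RSCU

Vertebrate mitochondrial code (NCBI table 2) throughout, embedded via
Biopython. RSCU_ij = x_ij /((1/n_i) Σ_j x_ij); stop codons are counted
separately and excluded; a trailing 1–2 nt incomplete stop is dropped
before counting; codons containing ambiguity are skipped with a tally.
Within each amino-acid family RSCU sums to the family size — a property
test. Single-codon amino acids get RSCU 1 whenever observed.

## tRNA cloverleaf folding

The folder performs an exhaustive, deterministic search over arm
geometries rather than thermodynamic folding. Search space: acceptor 6–8
pairs; DHU arm absent or 3–4 pairs with a 4–12 nt loop; anticodon stem 4–6
pairs with a fixed 7 nt loop (anticodon = center three); variable loop
3–23 nt; T-arm 4–5 pairs with a 4–9 nt loop. The decomposition tiles the
input exactly (`flatten(structure) == sequence` is an invariant). Score =
2·(Watson–Crick) + 1·(wobble) − 1·(mismatch) over all stem pairs; the DNA
alphabet is used throughout, so wobble is G·T. Ties prefer arm lengths
closest to the canonical (7,4,5,5), then the smallest variable loop, then
lexicographic geometry order — identical input always yields the identical
structure. Admissibility caps mismatches at 1 per stem (2 in the acceptor);
a sequence with no admissible geometry is reported unfoldable rather than
forced. An optional anticodon hint pins the anticodon-loop placement, which
is how genome-annotated anticodons are used.

The cross-species comparison requires a shared anticodon (the tRNA's
identity), reports arm-length and variable-loop ranges, pooled per-arm
pair-class tallies, and the count of species sharing the modal
(arm-lengths × pair-classes) profile; ≥10 pooled non-Watson–Crick pairs
raises a "high variation" flag.

## Control-region analyses

Tandem repeats: for every period p (default 1–60), maximal runs of
`seq[i] == seq[i−p]` define repeat spans with fractional final copies;
non-primitive motifs are dropped (their smaller-period description is
reported instead), and overlapping reports collapse to the longest span —
at equal span the smallest period — per locus. Only exact repeats are
supported; alignment-scored fuzzy repeats are out of scope, as the repeats
this family's control regions carry are exact and the fractional-copy
notation covers partial final copies. Every reported repeat re-validates
against the sequence (property-tested).

Motif scan: IUPAC-aware exact matching with overlapping hits, 1-based
starts, optional reverse-complement search. Stem-loops: for every loop
placement (4–23 nt) the stem grows outward while pairs are Watson–Crick or
wobble (mismatches terminate it), and hairpins with 2–7 pairs are reported
ranked by stem length then fewest non-WC pairs. No free-energy model is
attached; the heuristic finds the same class of short stable hairpins that
mark the light-strand replication origin.

## NG86 Ka/Ks

Synonymous sites per codon: at each position, the fraction of non-stop
single-nucleotide neighbors preserving the amino acid (mutations to stop
codons are excluded from the denominator, mirroring the path rule below);
site totals average over both sequences, and S + N = 3·(codons compared)
exactly. Differences between codons differing at 2–3 positions average
over all orderings of the changes, excluding orderings that pass through a
stop codon; if every ordering is blocked, the changes count as
nonsynonymous. Codon pairs containing gaps, ambiguity or stop codons are
excluded pairwise (pairwise deletion, not complete deletion). Correction:
Jukes–Cantor `d = −(3/4)·ln(1 − (4/3)p)`, undefined ("saturated") at
p ≥ 3/4; the Ka/Ks ratio is undefined when Ks is 0 or either rate is
saturated. The per-gene summary reports mean ± sample SD over defined
ratios, excluded pairs counted, genes ordered by ascending mean. The whole
counting path is verified against an independent brute-force enumerator
over all sense-codon pairs.

Alignment is protein-guided: Needleman–Wunsch on the translations (match
+1, mismatch 0, gap −1; tie-break diagonal first, then gap in the first
row) back-mapped to whole-codon gaps. Internal stop codons warn and align
as a mismatch state.

## Distances and the tree stage

K2P: d = ½·ln(1/(1−2P−Q)) + ¼·ln(1/(1−2Q)) with P/Q the transition/
transversion proportions over unambiguous columns; non-positive log
arguments report saturation. The tree stage is Saitou–Nei neighbor joining
over K2P distances on the concatenated protein-coding supermatrix — an
explicit simplification standing in for model-based maximum likelihood,
chosen because it is deterministic, exact on additive matrices (property
tested at 5–8 taxa, and cross-checked against an independent NJ
implementation), and sufficient for clade-level checks on synthetic data.
Q-criterion ties break by label order; negative branch lengths clamp to
zero with a warning.

## Synthetic-data generator

The generator's defaults are the study conditions of the reference turtle
mitogenome: 16,796 bp, the bundled 37-gene layout (hence exactly 6
overlaps/13 bp and 19 spacers/124 bp), genome A+T 62.16% with AT skew
0.197 and GC skew −0.400, partition A+T of 61.26/63.82/61.47/68.52% (PCG/
tRNA/rRNA/CR), control-region repeats (ATTAT)₈, a 49 bp motif ×2, (AT)₇
and (TATTA)₂₀ separated by 151/781/87 bp spacers, a planted GACATA motif
and a 5-pair hairpin. A single integer seed drives one RNG; identical
(spec, seed) gives byte-identical FASTA/GenBank output (GenBank records
carry a fixed date for this reason).

Numerical choices worth knowing:

* Base frequencies per partition follow from (A+T, AT skew, GC skew)
  targets. For protein-coding genes, codons are sampled base-wise with
  stop-codon rejection; because mitochondrial stops are A/T-rich this
  rejection depresses realized A+T, so the generator solves (by bisection,
  exactly) for the nominal frequencies whose stop-rejected expectation hits
  the target. The control-region fill rate is likewise solved analytically
  around the planted pure-A/T repeats. Realized genome A+T lands within
  ±0.01 of target (documented tolerance; binomial SD alone is ~0.004).
* tRNA stems sample one strand and complement the other, which is
  A+T-neutral and flips skew; loops sample directly. Designed geometries
  are the canonical-closest admissible ones, DHU-less below 64 nt (as in
  vertebrate mitochondrial tRNA-Ser(AGY)).
* Planted repeats are guarded by flank bases chosen to break the period,
  so the repeat finder recovers (motif, period, copies, start) exactly.
* Where layout features overlap (six loci), the later-written feature owns
  the shared bases and CDS start codons are re-imposed afterwards; a tRNA
  whose edge was overwritten is flagged "clobbered" in the truth record,
  and truth always reflects the emitted sequence (re-validated at
  generation time).
* Divergent CDS pairs apply per-position synonymous/nonsynonymous changes
  with the planted rates, never creating stops, classifying against the
  current codon; realized counts are recorded. `mutate_genome` extends
  this to whole genomes (codon-aware in genes, uniform elsewhere) to build
  related families for the comparative stages.

What the generator does **not** emulate: real sequence homology between
species (family members derive from one ancestor by i.i.d. substitution,
not evolution along a tree), rate heterogeneity among sites, indels,
duplicated control regions, and base modification. Tests passing on
generator output therefore validate the arithmetic and detection machinery
under controlled truth, not annotation quality or phylogenetic accuracy on
real divergent genomes.

## Problem sizes

The test suite and the reproduction script run at deliberately modest
sizes chosen to exercise every code path with comfortable statistical
margins: one 16.8 kb genome per seed, 50 replicate divergent pairs of 100
codons for the dN/dS direction check, 20 random additive matrices of 5–8
taxa for NJ recovery, and a three-genome family for the comparative
stage.

## Known limitations

* Stop-codon conventions differ among published tools; the site-counting
  exclusion used here (with S+N = 3L preserved) matches the path-exclusion
  rule but will differ in the third decimal from implementations that
  count stop mutations as nonsynonymous sites.
* The cloverleaf admissibility caps (≤1 mismatch per stem, ≤2 in the
  acceptor) reject heavily degenerated real mitochondrial tRNAs that
  dedicated covariance-model tools would still fold.
* The repeat finder is exact-match only and reports primitive motifs; a
  diverged repeat array (copies with point mutations) appears as several
  shorter exact repeats rather than one fuzzy array.
* The tree stage assumes a complete, saturation-free distance matrix and
  equal-length (or trimmed) CDS when run through the report pipeline;
  divergent annotations should go through the pairwise aligner instead.
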