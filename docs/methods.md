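# Methods

## Study design being modelled

The pipeline analyses small-RNA deep-sequencing libraries from early
*Drosophila* embryos fractionated on sucrose density gradients. Two
developmental stages bracket the maternal-to-zygotic transition (0–1 h and
7–8 h after egg laying); each stage contributes an unfractionated total-RNA
library (UF) and four gradient fractions — mRNP (ribosome-free messenger
ribonucleoprotein), 60S, 80S/monosome and polysome — giving ten multiplexed
samples. Reads are 36 nt: a 4-nt sample barcode, a 15–29-nt insert and as
much of the 25-nt 3′ adapter (`ATCTCGTATGCCGTCTTCTGCTTGT`) as fits. The
4-nt barcode length is a reconstruction: with 36-nt reads and a 25-nt
adapter it is the only length for which full-adapter trimming yields a 7-nt
minimum insert and stepwise trimming yields 8–28-nt inserts, as the original
processing reports.

## Adapter-trimming cascade

Trimming operates on the 32-nt remainder after barcode removal and is a
total function with seven outcomes:

1. **Full adapter** — the leftmost exact occurrence of the whole adapter;
   the prefix is the insert, accepted from 7 nt (shorter → `rejected_short`).
2. **Stepwise** — otherwise the adapter is shortened from its 3′ end one
   base at a time down to 4 nt and compared with the remainder's 3′
   terminus; the longest matching prefix wins (inserts 8–28 nt).
3. **Mismatch retry** — otherwise both searches are repeated allowing up to
   2 substitutions over an adapter match of at least 10 nt. Candidates are
   ranked by fewest mismatches, then longest adapter match, then leftmost
   position. No indels are allowed here; at these match lengths a
   2-substitution cap keeps the false-trim rate negligible.
4. **Screen** — any trimmed insert with ≥ 90 % A is rejected as poly(A);
   more than one N rejects the insert. (These thresholds are package
   choices: the original filter names "poly(A)" and "multiple Ns" without
   definitions; single-N inserts survive but can only map in mismatch
   tiers.)

Reads with no candidate are `untrimmed`. Inserts of 15–29 nt are collapsed
to unique sequences with per-sample counts. The retention window is applied
as published even though a 29-nt insert leaves only 3 nt of visible adapter
in a 36-nt read and is therefore untrimmable — such reads surface as
`untrimmed`, which the round-trip tests account for by conditioning on
≥ 4 nt of visible adapter. The cascade is validated against an independent
brute-force search over all (cut position, adapter length, mismatch count)
candidates under the same precedence.

## Hierarchical annotation

Each insert is assigned to exactly one of ten categories in fixed priority
order (rRNA, miRNA hairpin, tRNA, miscRNA, ncRNA, transposon, transcript,
intron, pseudogene, intergenic) or left unassigned. The sweep is
**tier-major**: all categories are tried at 0 substitutions before any
category is tried at 1, then 2, then 3 — so a 3-mismatch rRNA hit can never
pre-empt an exact miRNA hit; category order breaks ties within a tier. A
match is an end-to-end alignment of the insert inside a reference sequence
(substring with ≤ t substitutions), on either strand; the strand is
recorded because antisense matches carry the ping-pong and cluster
strand-bias signal. The stored multiplicity is the number of reference hits
at the winning tier across all categories and both strands, and serves as
the mapping-site count for the normalised ping-pong spectrum. tRNAs are
matched in their CCA-appended mature form.

QC alignment against the miniature genome is a separate ladder — exact,
1 error (substitution *or* single indel, via edlib's infix alignment), 2
substitutions, 3 substitutions, unmapped — kept independent of category
assignment.

Remapping is exact-only: transposon-assigned inserts receive a repeat-family
label when they occur verbatim in a family consensus, and
transposon/intergenic inserts receive a cluster flag (id and strand of their
first exact genomic placement inside a piRNA-cluster interval). Coordinates
are 0-based half-open internally; reports use 1-based read positions.

## miRNA quantification and the four polysome-association groups

A read counts toward a mature miRNA when it matches the hairpin exactly and
its 5′ end lies within ± 3 nt of the annotated mature 5′ end (the isomiR
window; configurable). RPM uses the number of category-assigned reads per
sample as denominator — a package choice that is stable under unmapped-read
contamination. miRNAs reaching 50 RPM (inclusive) in at least one sample
are kept.

Stage fold changes are `log2((RPM_7–8h + 10) / (RPM_0–1h + 10))` per column
(Tot, mRNP, 60S, 80S, Poly); the 10-read pseudocount damps low-count noise
and bounds every fold change by `log2((1e6 + 10) / 10) ≈ 16.6`.

The 4-group rule, with inclusive threshold τ = 1.0 on the log2 scale:

* `|Tot| < τ` → **G2** (unchanged in unfractionated embryos);
* otherwise let d = sign(Tot); a fraction column *supports* the change if
  `d·value ≥ τ` and *opposes* it if `−d·value ≥ τ`;
* no support and ≥ 1 opposition → **G4** (discordant localisation);
* else **G1** (d > 0) or **G3** (d < 0).

τ = 1.0 and the rule itself are a reconstruction validated by exact
reproduction of the packaged published table: all 94 row labels match and
the group sizes are 41/19/29/5, with the published G1 substructure (17
mRNP-enriched, 9 with no enriched fraction) recovered.

Satellites: the abundance panel is the union of each sample's top-10
hairpins by hairpin-share (whether the original panel used a union or
another set operation over the 50 picks is unstated; the union is
implemented and no panel-size constant is asserted). Fraction distributions
express each miRNA as percentages over the four fractions of a stage
(all-zero rows are flagged undefined). Cluster co-sedimentation uses
Euclidean distances between fraction-distribution vectors with
complete-linkage clustering (scipy), a newick dendrogram export, and the
summary statistic mean(within-cluster) − mean(between-cluster). Editing
candidates aggregate reads at Hamming distance 1 from a mature sequence by
(miRNA, position, ref→alt), with defaults of ≥ 10 supporting reads and
≥ 10 % supporting fraction; the output notes that reads alone cannot
distinguish editing from a genomic SNP.

## piRNA/siRNA signatures

Transposon-derived reads partition by length: 21 nt → siRNA, 23–29 nt →
piRNA, 15–20 and 22 nt → other (the published size classes name only 21 and
23–29). The ping-pong spectrum accumulates, for every plus-strand read with
5′ end at p and minus-strand read with 5′ genomic coordinate q on the same
reference, the offset `d = q − p + 1`, so an exact 10-nt 5′ overlap scores
d = 10. Counting is all-vs-all within a reference (quadratic, fine at desk
scale) rather than best-partner; a 1/multiplicity-weighted variant divides
each pair by the product of the two reads' mapping-site counts, and both
variants coincide when every read maps uniquely. Base-bias matrices cover
read positions 1–20 (which includes positions 1 and 10 for all piRNA-sized
reads), with T displayed as U; an option restricts the input to reads
participating in exact 10-nt overlap pairs. Strand profiles bin 5′ ends of
cluster-resident reads into 50 bins per cluster and report the per-cluster
plus/(plus+minus) bias; reads outside all clusters are tallied, and empty
clusters yield an undefined (NaN) bias.

## Synthetic-data generator

The generator emulates the study layout, not any particular genome. From a
single seed it derives: random reference sequences per category (hairpins
of 90 nt with one 22-nt mature at offset 15, tRNAs stored CCA-appended,
transposon consensi of 400 nt, etc.); a two-contig genome whose first
contig carries one copy of every reference and whose second carries two
piRNA clusters assembled from transposon copies in both orientations
(emulating a dual-strand cluster such as 42AB) plus one intergenic stretch;
and multiplexed libraries whose per-sample category mixtures follow a
configurable composition table. The default composition encodes the
biology the pipeline is meant to resolve — piRNAs abundant early and
polysome-shifted, siRNAs rising post-MZT and mRNP-enriched, tRFs
mRNP-enriched, rRNA fragments tracking ribosome content — purely through
the table, not hard-coded behaviour.

Ping-pong reads are constructed explicitly: an initiator (plus strand, 5′
at p) and responder (minus strand, 5′ at p + 9) overlap by exactly 10 nt,
with lengths drawn uniformly from 23–29 nt. Because the initiator's first
base and the responder's tenth base are complementary views of the same
genomic position, the 1U and 10A biases cannot be independent for a pair;
the generator therefore draws the pair's anchor from genomic T positions
with probability (u1_bias + a10_bias)/2 (defaults 0.9/0.9, hence exactly
0.9). This realises both biases exactly whenever the two are equal and —
unlike mutating read bases — keeps every read an exact substring of its
source, so tier-0 annotation recovery remains meaningful. Unpaired
background reads are placed uniformly on cluster copies, and pair anchors
are confined to single transposon copies so no read spans a copy junction.

What the simulator deliberately omits: sequencing errors and quality
modelling, expression heterogeneity within a category (sources are drawn
uniformly), secondary-structure-aware hairpin processing, and real genomic
repeat structure. Passing tests therefore demonstrate the correctness of
the pipeline's logic under the declared read model, not robustness to
sequencing noise or to reference ambiguity beyond what random sequences
produce.

## Problem sizes and numerical choices

The test suite simulates 2,000 reads per sample for the ten-sample
end-to-end run and 10,000 reads per sample for composition-recovery checks
(the ±2-percentage-point recovery band is a ≥ 4σ binomial bound at that
depth); ping-pong analyses use 1,000 pairs plus ~10 % background for
spectrum recovery and ≥ 2,000 responders for base-bias recovery. Null and
recovery properties of the spectrum are checked over 20 seeds. Percentage
tables are validated to sum to 100 within 1e-9; reference category
sequences must be at least 29 nt (the maximum insert length); sequence
comparisons are substitution-only except for the QC 1-error tier. All
randomness flows from a single integer seed through `numpy.random.Generator`,
and identical configurations reproduce byte-identical references, reads and
ground truth.

## Known limitations

* Quantities that require the original deposited libraries and full
  genome/annotation releases (total read counts, genome match rates,
  real composition tables, the real 42AB profile, the 263/94 detected
  miRNA counts) are not reproduced here; the packaged fold-change table is
  the only published data product shipped.
* The G4 rule is validated only against that table; whether the original
  grouping used additional criteria is unknowable from the publication.
* The annotation matcher is a direct substring/Hamming scanner, appropriate
  for desk-scale references; it is not a genome-scale indexed aligner.
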