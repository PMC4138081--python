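# Methods

## Scope and data model

mirforge implements the computational core of a deep-sequencing miRNA
survey: read QC and exact genome mapping, candidate hairpin extraction
from read stacks, the six-criterion annotation engine, genomic-context
statistics, and expression/phylostratigraphy analytics. All internal
coordinates are 0-based half-open on the forward strand; on-disk GFF3 is
1-based inclusive. Input DNA/RNA is normalised to uppercase DNA at the
I/O boundary. Alignments are exchanged as a 6-column TSV (tag, scaffold,
start, strand, count, n_loci) rather than SAM/BAM: they are produced
internally by exact matching, and the flat table keeps the pipeline
transparent and dependency-light.

## Read processing

A read passes QC iff it is ≥ 18 nt, its mean Phred error probability
(mean of 10^(−Q/10)) is strictly below 0.01, at most 4 bases have
Q < 10, and at most 6 bases have Q < 13. Rejection reasons are tallied
in that order, so the tally partitions all rejections. Passing reads are
collapsed to distinct tags with per-library counts, and mapped by exact
full-length matching on both strands (18-mer seed, full verification;
contract: every exact hit is found — checked against a brute-force
double-strand scan in the tests). Multi-mapping tags are kept with their
locus count; the single-locus decision is criterion 1's, at the
precursor level. Alignments overlapping ≥ 1 bp of a protein-coding exon
or any rRNA/tRNA/snRNA/repeat interval are excluded, strand-blind —
the most exclusionary reading of "mapped to annotated classes", chosen
deliberately and applied uniformly; the exclusion tally uses the
priority rRNA > tRNA > snRNA > repeat > exon.

## Candidate extraction and evaluation

Read stacks (single-linkage overlap groups per scaffold/strand) with
≥ 10 reads seed up to two 100-nt windows each: the stack read as the 5p
arm and as the 3p arm. Windows containing N are discarded. Within a
window, arm assignment is **read-driven**: with two or more stacks the
midpoint between the outermost stacks splits the arms; only a lone
stack consults the folded structure's main loop (the loop under the
deepest stem). We found fold-based arm splitting fragile — a weak
candidate flanked by random genomic sequence can fold "through" its
flank — whereas the read geometry is exactly the evidence the criteria
are about.

Each arm's modal mature is its count-weighted modal 5′ end plus modal
length (ties toward the 5′-most/shortest). The candidate is then
**trimmed** to [5p mature start − 2, 3p mature end + 2) and refolded;
MFE, duplex geometry and the locus count are measured on the trimmed
precursor. The MFE criterion concerns the precursor hairpin, not the
extraction window, so flanking sequence must not rescue (or sink) a
candidate.

Duplex geometry is computed from the trimmed structure: n_complementary
counts structure pairs joining 5p-mature to 3p-mature positions;
3′-overhangs are measured in the duplex alignment implied by the
outermost/innermost mature-to-mature pair and may be negative (recessed
ends). A uniform shift of one mature moves **both** 3′ overhangs in the
same direction (antiparallel geometry); criterion 6 demands exactly
2/2, with conservation (a seed-anchored catalog match) as the explicit
alternative.

Accepted overlapping candidates are deduplicated (most reads, then
lowest MFE, then leftmost); rejected candidates are retained so each
locus's failure set stays inspectable.

## Folding model

The built-in backend maximises summed pair pseudo-energies (G:C 3.0,
A:U 2.0, G:U 1.0; minimum loop 3) over nested structures — a
Nussinov-style O(n³) DP, exact for its objective (verified against
exhaustive enumeration for n ≤ 30). The traceback is deterministic: at
each step position i is paired with the **largest** partner achieving
the optimum, which resolves the many ties of wobble-rich stems into the
canonical outermost ladder. The weights are pseudo-energies, not a
thermodynamic parameter set; the −21 kcal/mol threshold applies to
whichever backend is active, and the synthetic generator calibrates its
plants against the active backend. RNAfold can be swapped in
(`fold(seq, backend="vienna")`) with the identical contract.

## Genomic context

"Gene region" means the gene span (first exon start to last exon end),
introns included. Location classes: exonic (any exon overlap of the
host), intronic sense/antisense (inside the span, by strand match),
else intergenic with the distance to the nearest span; a
boundary-spanning precursor is classed by majority overlap and flagged.
The window null tiles each scaffold from position 0 into contiguous
79-bp windows (final partial window kept iff ≥ half length), extends
each by the flank (0/500/1000/2000 bp, clamped), and counts ≥ 1 bp
gene-span overlaps; a sense-strand-restricted variant is exposed because
the published comparison is ambiguous on that point. Proportions are
compared with the uncorrected Pearson χ² on the 2×2 table, 1 df
(expected counts < 5 raise a flag); a Yates-corrected variant is a
one-line config away but uncorrected is the declared default. Clusters
chain consecutive same-scaffold precursors with end-to-start gaps
≤ 10,000 bp inclusive (single linkage, strand-blind), verified against
brute-force transitive closure.

## Expression and phylostratigraphy

Guide/star: if the arm read totals differ by **more than** 5-fold
(ties at exactly 5.0 are co-mature; a zero arm is an infinite ratio),
the larger arm is the guide; otherwise both arms are co-mature. Matures
under 50 reads total stay in the annotation as star but leave the
expression-analysis set. RPM is count / library mapped reads × 10⁶.
CV is the sample standard deviation (n−1) over the mean of RPM.
Specificity screens run after merge-group averaging (the two mantle
libraries average into one pseudo-sample): specifically-high iff RPM ≥
5× every other sample (and > 0), specifically-low iff ≤ ⅕ of every
other sample, thresholds inclusive and the two screens independent.
Co-expression is Pearson r with a two-sided P from
t = r√((n−2)/(1−r²)) on n−2 df; co-expressed iff r > 0.8 and
P < 10⁻⁴.

Phylostratum assignment anchors the seed (positions 2–8) — it must be
identical — and scores ungapped identity over the longer sequence;
≥ 0.8 assigns the entry's rank (ties: highest identity, then oldest
rank), otherwise the mature is novel and receives max rank + 1, the
youngest stratum. miRPAI(stage) = Σ psᵢeᵢ / Σ eᵢ over raw counts
(an RPM-weighted variant sits behind a flag; "read number" is the
stated weight). It is scale-invariant per stage, bounded by the rank
range, and undefined (an error) for an all-zero stage.

## The synthetic-data generator

The generator is the study-condition oracle. A planted hairpin is
[2-nt lead][L-nt 5p arm][loop][3p arm = revcomp(5p arm)] with defaults
L = 32, loop = 15 (79 nt, the average precursor length in this kind of
survey, range ~71–91). The 5p mature starts 2 nt in; the 3p mature runs
to the hairpin 3′ end; this realises exact 2-nt 3′ overhangs at both
duplex ends. Three stem pairs are converted to G:U wobbles — real stems
have them, and they break the perfect self-complementarity that would
otherwise let arm reads map antisense onto the opposite arm. Each plant
is written with a 2-nt tail so the trimmed candidate never ends in
uncontrolled genomic sequence.

Counts per (plant, library, arm) are negative binomial (dispersion 8)
around the plant's expression profile; the guide:star mean ratio is
10:1 (1.5:1 for co-mature plants, exercising the both-retained path).
Expression profiles are phylostratum-structured: old ranks flat across
development, young ranks peaked at mid-development (the structure the
miRPAI analysis is designed to detect); two true plants are organ
markers (mantle, adductor muscle) so the specificity screens have
designed positives. 5′-end heterogeneity is ±1-nt jitter at rate 0.05 —
published data do not quantify this, so it is an exposed noise knob,
not an inference. 2% of reads carry five Q9 bases (QC fodder);
background reads (5%) are drawn from annotated intervals and random
genome, away from planted loci (they model degradation of annotated
classes, not the planted hairpins — a one-read contaminant on a
deliberately tiny decoy stack would scramble its label).

Decoys violate exactly one criterion: (1) the hairpin ± 4 nt duplicated
at a second locus; (2) an all-wobble G:T stem over {G,T} with all-G loop
and tail — the total T count equals the stem length, so no structure
can score better than the −20 kcal/mol ladder while 17 pairs still join
the matures; (3) guide 5′ ends split 50/30/20 across three start
positions; (4) total emission clamped below 50 reads (both arms
observed); (5) Watson–Crick stem with 6–8 duplex mismatches (12–14
pairs remain, MFE still strong); (6) star reads shifted +2 nt,
breaking both overhangs. Every plant — true and decoy — is validated at
build time against the actual extraction + criteria engine with its
intended read stack and redrawn until the verdict matches its label
(the generator also enforces genome-wide mature-tag uniqueness, since
restricted-alphabet decoy stems occasionally collide). Two further
generator guarantees keep count-based labels exact under NB sampling:
criterion-4 decoys are clamped below 50 total reads, all other plants
floored at 60; and decoys other than criterion 3 emit jitter-free 5′
ends so a tiny stack cannot pick up an incidental criterion-3 failure.

What the generator does **not** emulate: sequencing substitution
errors, adapters, piRNA populations, isomiR 3′ heterogeneity, GC/length
biases of real libraries, and realistic genome repeat structure. A
passing recovery test therefore shows the pipeline implements its rules
correctly and discriminates the planted signal classes — not that those
rules are optimal for real oyster libraries.

## Problem sizes and numerical choices

The default study is 3 × 70 kb scaffolds at 40% gene density, 40 true
plants + 60 decoys, 21 libraries, ~50 k reads — sizes chosen so a full
run takes seconds while every criterion still has ten decoys to
discriminate. At this planting density (one locus per ~2 kb) incidental
10-kb adjacency among accepted precursors is common, so study-level
cluster fractions mostly reflect placement density; designed cluster
chains are therefore given 10-kb exclusion bands (making them exactly
recoverable), and the cluster detector itself is validated against the
exact transitive-closure oracle on random layouts. Determinism: a
single integer seed derives every RNG; reruns are byte-identical (no
timestamps, sorted JSON, fixed orderings). Degenerate inputs error
loudly rather than guess: zero-margin χ² tables, all-zero miRPAI
stages, zero-variance co-expression vectors (flagged, not co-expressed),
matures shorter than the seed.

## Known limitations

The built-in energies are not thermodynamic; absolute MFE values are
only comparable within a backend. Mature boundaries use the modal 5′
end + modal length, summarising but not cataloguing isomiRs. Criterion 3
is applied per arm (the published wording does not say per-arm or
per-precursor); the 0.8 consistency threshold is a declared default
surfaced in every verdict. The exclusion rule is strand-blind and
1-bp-strict by choice. Exact full-length mapping stands in for
mismatch-tolerant alignment: divergent loci that a seeded aligner would
still hit are invisible here.
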