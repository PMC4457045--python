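# Methods

## The model

Plant phased secondary siRNAs (phasiRNAs) arise when a 21- or 22-nt
miRNA/siRNA guides cleavage of a precursor transcript, RDR6/SGS3 convert the
downstream fragment to dsRNA, and DCL4 (or DCL3b/DCL5 for the 24-nt class)
dices it processively from the cleavage end. The products therefore appear in
head-to-tail increments of the register length *r* (21 or 24 nt): the 5' ends
of the sense-strand siRNAs occupy a single residue class modulo *r* anchored
at the cleavage site, and each antisense partner sits 2 nt upstream of its
sense read (the 2-nt 3' overhang left by the dicer). `phasekit` detects such
loci from collapsed small-RNA reads placed on a genome or transcriptome by
exact, full-length matching.

### Read placement

Reads are placed with zero mismatches and no gaps; reads with more than
`max_hits` (default 6) placements are discarded entirely, and each retained
multi-mapping read contributes its full count at every placement (no
fractional weighting). The RPM denominator is the "cleaned" library total:
reads surviving adaptor trimming, the 18–34-nt length bounds and rRNA
filtering, counted *before* the multi-hit mapping filter. rRNA filtering is
exact-substring matching of the read against either strand of the rRNA
references, which at zero mismatches is equivalent to alignment-based
removal.

### Phase registers and the window scan

Minus-strand alignments receive a +2 offset on their leftmost coordinate so
that a perfect duplex partner lands in its sense read's register. Windows of
*m* = 9 register cycles (189 nt at *r* = 21; 216 nt at *r* = 24) slide along
each reference with a step of three registers (63 / 72 nt), so consecutive
windows overlap by six cycles; overlapping placement was chosen over
disjoint 63-nt-separated windows because gaps would miss loci straddling a
boundary. A window is eligible when it holds ≥ 10 unique reads, strictly
more than half of them register-length, and ≥ 3 register-length reads in the
best phase. For each window all *r* candidate phase offsets are tallied and
the offset maximizing the in-phase occupancy is kept (ties to the smallest
offset index).

### The phasing statistic

The window is modeled as *rm* positions of which *m* belong to one register.
With *n* the number of distinct register-length reads in the window and *k*
the number of the dominant register's cycle slots occupied by at least one
of them, the probability of observing *k* or more occupied in-phase slots by
chance is the hypergeometric tail

    p(k) = Σ_{X=k}^{min(n,m)} C((r−1)m, n−X) · C(m, X) / C(rm, n).

Note the two counts deliberately differ in granularity: *n* counts unique
reads (sense and antisense duplex partners are distinct sequences), while
*k* counts occupied slots, which bounds it by *m* as the formula requires —
a perfect duplex locus would otherwise give k = 2m and leave the
distribution's domain. *n* is clamped to *rm* for pathologically dense
windows. The tail is evaluated with exact integer binomials and converted
to float once, so it is correct to full double precision. The upper limit is
min(*n*, *m*): the point mass is zero beyond either bound.

A 21-nt window is positive iff p < 0.001 (strict, per the detection
convention this tool follows). 24-nt windows are called by the log phasing
score instead:

    score = (occupied − 2) · ln(1 + 10·ΣP / (1 + ΣU)),   occupied ≥ 3, else 0

where ΣP is the total read count in the dominant register across the
window's cycles, ΣU the number of unique register-length reads outside it,
and `occupied` the number of in-phase cycle slots holding a read. The cutoff
is score ≥ 15 (inclusive: it is a cut-off value, and the exponent uses the
occupied-register count, which is how the score's symbol legend defines it,
rather than the k of the hypergeometric).

Positive windows merge into a locus when they lie on the same reference,
their starts differ by a multiple of *r*, their chosen phases share one
residue class, and their spans touch or overlap; the locus keeps the union
extent, minimum P-value, maximum score and the union of in-phase member
reads. Because window starts sit on the step grid, a called locus can
overhang the true phased region by up to about two steps; downstream steps
account for this (see trigger search).

**Known inflation.** The statistic is the plain tail at the *maximized* k;
no correction is applied for testing r candidate offsets per window (the
standard formulation does not apply one either). Consequently, reads that
cluster off-phase — e.g. degradation products jittered by a few nucleotides,
which reoccupy few distinct residue classes — can occasionally reach
p < 0.001 with k of ~5 slots. The synthetic zero-fidelity control makes
this visible: typically one to two windows per 30 fully corrupted loci cross
the cutoff. Users should treat borderline calls (k ≤ 5) with caution.

### Genomic classification and gene-level consolidation

Loci are classified against the longest isoform of the overlapping gene
(largest extent overlap; ties to the smaller gene id) using the *footprint*
— the union of in-phase member-read intervals — rather than the window
extent, which can overhang annotation by grid chance: footprint entirely in
exons → `exon`, entirely in introns → `intron`, both → `exon_intron`, no
gene overlap → `intergenic`. Loci sharing a gene merge into one record.
Intron-class loci can be checked against an RNA-seq BedGraph: mean coverage
< 1 read/nt over the phasiRNA-producing intron supports a spliced
("bona fide") intron, ≥ 5 reads/nt supports retention, the band between is
left unknown. The 1/5 thresholds are this package's choices — the
qualitative distinction they encode is "no" versus "good" coverage.

### Trigger prediction

sRNA/target duplexes are scored with the plant-target penalty scheme:
mismatch 1.0, G:U wobble 0.5, one-base bulge 2.0, all penalties doubled at
sRNA positions 2–13 (the pairing core), alignments ungapped or with a single
bulge on either strand. The predicted cleavage site is the target base
paired to sRNA position 10. Candidate triggers are 21/22-nt reads above
10 RPM aligned against the locus flanks (200 nt on each side, extended
150 nt into the called locus to absorb the window-grid overhang) at score
≤ 4; both orientations are scanned because precursor orientation is unknown
for intergenic loci. A candidate is *in phase* when its cleavage coordinate
falls on the locus register (N × r from the phase anchor). Out-of-phase
candidates are dropped unless they match a known mature miRNA (≤ 2
mismatches, length ± 1) from an established trigger family (an editable
whitelist ships with the package) or carry degradome support (≥ 2 degradome
5' ends within ± 1 nt of the cleavage site). Per locus, two distinct 21-nt
hit sites — counted as cleavage-position clusters, so bulge/offset variants
of one site are not double-counted — indicate the two-hit model; a single
22-nt hit the one-hit model; a lone 21-nt hit stays unclassified. Putative
novel miRNAs can optionally be screened by folding ± 150 nt of genomic
context (RNAfold, if installed): the sRNA must sit in one arm of a stem-loop
with ≥ 16 bases paired and at most one ≥ 4-nt internal loop; without a
folding engine the verdict is `no_engine` and candidates stay putative.

### Target prediction

phasiRNAs (register-length member reads of positive loci at ≥ 10 RPM) are
aligned against the transcriptome with the same penalty scheme; hits at
score ≤ 3 are reported and hits at ≤ 1.5 flagged stringent. Both transcript
orientations are scanned: phasiRNAs derive from both strands of the dsRNA
precursor, so a sense-strand phasiRNA pairs the antisense of its own
precursor — restricting to one orientation would hide half of the cis
signal. Targets are classified cis (the originating transcript),
same_family (shared entry in a user-supplied gene→family map; genes missing
from the map are singleton families), or trans. Without a user
transcriptome the pipeline derives one from the annotation (unspliced gene
spans) plus noncoding records for intergenic loci (± 100 nt).

### Differential phasiRNA production

Per locus key (gene id, else coordinates), register-length siRNA abundance
is compared between libraries as ratio = (RPM_b + ε)/(RPM_a + ε) with
ε = 0.1 RPM (zero handling is unspecified in the convention this follows; a
small pseudocount keeps ratios finite and the comparison antisymmetric).
PHAS-status transitions take precedence (`gained_PHAS` / `lost_PHAS`), then
the plain five-fold rule (`induced` / `suppressed`), else `stable`. No
significance test is attached — the analysis is a descriptive fold change.

## The synthetic-data generator

The generator emulates the statistical structure of real plant sRNA
libraries at desk scale. Defaults (the package's study conditions): a 200-kb
random genome; 24 genes of 2–5 exons (exons 280–520 nt, introns 300–600 nt,
all plus-strand), the last gene a structural duplicate of the first at 88 %
identity with transition-biased substitutions (the dominant class between
recent paralogs), giving one two-member family; 30 planted 21-nt loci
(8 exonic, 7 intronic, 7 junction, 8 intergenic — one locus per host gene)
plus two intergenic 24-nt loci; 10 duplex cycles per locus with
first-cycle count 2000 and geometric decay 0.8, balanced strands with a
±30 % count wobble; a planted trigger per 21-nt locus (22-nt one-hit or
21-nt two-hit with equal probability) whose complementary site is written
into the genome so that cleavage falls exactly on the first phasiRNA 5' end;
phasing fidelity 0.9 (each read independently jittered ± 1–10 nt with
probability 0.1); 400 uniform background reads with a 21-nt-dominated length
mix (~30 % of the library's unique reads); 5 % rRNA contamination drawn from
a bundled synthetic rRNA stub; and a degradome library with 20 reads at
every true cleavage site. All randomness flows from one seed and outputs are
byte-identical per seed.

What the generator does **not** model: sequencing errors, composition bias,
realistic transcriptome expression, minus-strand genes, spliced-transcript
phasing (loci are planted in genomic coordinates), and trigger biology for
the 24-nt class. Passing recovery tests therefore demonstrates the
correctness of the statistics and bookkeeping under the stated geometry, not
performance on real libraries with those complications.

Recovery is scored by ≥ 50 % overlap of the truth span (a pure artifact
policy; the original analyses had no truth set). On the default conditions
the pipeline recovers 30/30 planted 21-nt loci in all four classes and both
24-nt loci at precision 1.0, recovers 100 % of planted triggers with correct
flank, phase and model label, and reproduces the cis / same-family targeting
pattern with zero stringent trans predictions.

## Numerical and design notes

- Coordinates are 0-based half-open everywhere inside the package; GFF3 and
  SAM are converted at the I/O boundary.
- The hypergeometric tail uses exact integer arithmetic (`math.comb`); the
  P-value is cached per (n, k, m, r).
- Phase-offset ties break to the smallest offset; duplicate placements of a
  read (same sequence, start, strand) are counted once in abundance sums.
- The duplex aligner enumerates all registrations and single-bulge variants
  vectorized over offsets; two edge offsets of the sRNA-bulge variant are
  computed scalar. It is tested against exhaustive enumeration.
- The aligner's score is not invariant under joint reverse-complementation
  (a G:U wobble reverse-complements to a C:A mismatch and the 2–13 core does
  not mirror); the invariant that does hold, and is tested, is
  orientation-scan mirror consistency.
- Detection is exactly invariant under translations by the window step;
  translations by one register keep the locus and its phase residue but may
  shift the called boundary by up to one step (the window grid does not
  follow the reads).
- Problem sizes in the test suite and the acceptance script (200-kb default
  genome, 60-kb auxiliary datasets) were chosen so a full run completes in
  about a minute on one CPU while every locus class, trigger model and
  target relation is exercised.
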