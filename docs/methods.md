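# Methods

`remodelseq` analyses how a chromatin remodeler shapes transcription-factor
(TF) site selection, from three complementary fragment-level assays: ATAC-seq
(accessibility), capture MNase-seq (nucleosome dyads at selected loci) and
ChIP-seq (TF occupancy). Every statistic in the package operates on plain
fragment intervals (chrom, start, end) derived from paired-end reads, with
each read pair collapsed to a single fragment spanning its outer-most
coordinates. Coordinates are BED-style 0-based half-open throughout; the
center of `[start, end)` is `floor((start+end)/2)`, and the midpoint of a
fragment of length L is `start + L // 2`.

## Signal model and normalization

Raw signal at a locus is the number of fragments overlapping (mode
`fragment`) or with midpoint inside (mode `midpoint`) a window centered on
the peak. Counts are normalized to **fragments per 10 million library
fragments** (`scale = 1e7`). This is the unit in which the classification
threshold "30 normalized reads" is expressed; at a typical ATAC library of
5×10⁷ fragments on a mammalian genome, random background contributes ~5–10
normalized reads to a ±1 kb window, so the threshold separates background
from peak-level signal. The unit is a package convention — alternative units
rescale the threshold but not the classification logic.

Metaplot matrices (anchors × position bins) place each in-window fragment
as exactly **one event at its midpoint** (clipped into the window in
`fragment` mode). This makes the matrix total equal to the windowed count —
a conservation property the tests assert — at the cost of not spreading a
fragment's body across bins the way per-bp coverage tracks do. Heatmap rows
are ordered by descending row sum for reproducibility.

## Differential peaks

Per peak, replicate counts are pooled within condition and tested with a
two-sided **Fisher exact test** on the 2×2 table (in-peak vs rest-of-library
fragments per condition), followed by Benjamini–Hochberg FDR across peaks.
A peak is `increased` when FDR < 0.01, the pooled normalized fold change
exceeds 2, **and** the replicates agree in direction — every replicate of
the higher condition above the other condition's pooled normalized mean and
vice versa; `decreased` is symmetric. The deliberate conservatism of three
stacked gates mirrors the common FDR + fold-change reporting convention;
on overdispersed null data the Fisher p-values alone would be
anticonservative (they assume Poisson sampling), and it is the fold-change
and direction gates that keep the false-call fraction within the FDR budget
(verified by the permuted-null test at 3-vs-3 replicates, 2,000 peaks).
This statistic is a deterministic, dependency-free stand-in with the same
decision structure as a negative-binomial GLM; it does not share
information across peaks and is not recommended for single-replicate
designs with shallow counts.

## Peak classification

TF peaks are classed from pre-induction (t0) and post-induction (t12) ATAC
signal, rules applied in priority order:

1. `newly_accessible`: (t12_center + 1)/(t0_center + 1) > 2 in the ±200 bp
   center window **and** t12 flank (±1 kb) > 30 normalized reads;
2. `constitutively_accessible`: t0 flank > 30 normalized reads;
3. `constitutively_inaccessible`: everything else.

Choices made where the rules are open: the *constitutive* classes are
evaluated on the time-0 flank signal (constitutive refers to the
pre-induction state); the flank window includes the ±200 bp core; the
pseudocount is 1.0 normalized read on both ratio terms. Raising t12 center
signal can only move a peak toward `newly_accessible` (a monotonicity the
tests assert), and the three classes partition any peak set.

## Motif scanning and the potential-site construction

IUPAC consensus patterns (e.g. WGATAR for GATA factors, TGASTCA for AP-1)
are matched exactly per position; minus-strand hits are matches of the
reverse-complement pattern reported in plus-strand coordinates. An `N` in
the sequence matches only a fully degenerate pattern position. The analytic
per-bp match probability is the product over positions of allowed-base
probabilities, summed over the two strands (a palindromic pattern counts
twice, matching the two stranded hits the scanner reports); its reciprocal
is the expected spacing — 512 bp ≈ 500 bp for WGATAR, 4096 bp for TGASTCA,
under uniform base composition.

Potential (unbound) binding sites are built by extending each hit to 200 bp
about its center, removing **every** member of any mutually overlapping
group (the goal is isolated, unambiguous loci, so merging would defeat the
purpose), and removing loci overlapping observed ChIP peaks. Scanning-level
occupancy is then tested as a two-sided Mann–Whitney U on per-locus
normalized counts at the retained sites versus width-matched random
regions. The U test counts in a **±100 bp core window** although profiles
are drawn at ±500 bp: retained sites and sampled controls are each at least
200 bp apart, so core windows of distinct loci never overlap (keeping the
per-locus counts independent, as the rank test assumes), and signal from
excluded bound-peak footprints cannot reach into them.

## Nucleosome dyads

Mono-nucleosomal fragments are selected by length in the closed interval
[120, 170] bp; their midpoints approximate dyads. Dyad-frequency matrices
are midpoint histograms in (default) 10 bp bins around anchors. Duplicate
fragments are retained for capture MNase data (deep targeted coverage makes
duplicates expected), while ATAC inputs are assumed deduplicated upstream.

Reference normalization divides depth-scaled profile by depth-scaled
reference elementwise with a 0.5 pseudocount; depth scaling uses the two
library sizes, so genuinely doubled occupancy at equal depth reads as a
ratio of 2, and a pure depth difference reads as 1.

The phasing score summarizes a mean dyad profile as (i) **amplitude**: the
mean signal at the ±1 and ±2 expected nucleosome positions (default period
190 bp) minus the central value, clipped at zero — a flat profile scores 0;
and (ii) **period**: the autocorrelation-dominant lag searched over
120–260 bp.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, on
an i.i.d. random genome (default 2 chromosomes × 2.5 Mb at GC 0.41, the
human genome-wide value). Three locus archetypes (default 300 each) are
planted on a shuffled grid with ≥5 kb separation, each with a written-in
motif instance and a linked gene whose TSS sits 1.5 kb from the locus
center (300 bp for the promoter-like decreased archetype):

| archetype | ATAC t0 | ATAC t12 | KD×t12 | MNase geometry (t12) | gene log2FC |
|---|---|---|---|---|---|
| newly_accessible | 20 | 300 | ×3 | arrays ±190/±380 bp, occupancy 0.5 (control) / 0.85 (KD), NDR at center | +1.5 |
| constitutively_accessible | 250 | 260 | ×0.35 | arrays, occupancy 0.6 both conditions | −1.2 |
| constitutively_inaccessible | 5 | 10 | ×4 | one dyad on the motif (control), displaced +90 bp (KD) | +1.2 |

ATAC rates are mean fragments per locus per replicate; counts are
gamma-Poisson (negative binomial, dispersion 0.05 — a typical
between-replicate overdispersion for accessibility data) with uniform
background of 0.015 fragments/bp and insert sizes of 60–120 bp placed over
the locus NDR. MNase fragments have lengths Normal(147, 8) clipped to
[100, 200] bp and midpoints jittered Normal(0, 20) around the programmed
dyads, ~40 fragments per fully occupied dyad. ChIP fragments pile up at a
per-class bound fraction of loci (Poisson(80) fragments, midpoint jitter
sd 40, lengths 150–250 bp) plus a weak Poisson(`scanning_weight`) pileup at
every unbound motif instance and a uniform background; the emitted
true-peak intervals are ±300 bp, covering the full pileup footprint as a
peak caller would report it. Gene log2 fold changes are the archetype
coupling plus Normal(0, 0.3) noise.

Fragment sets carry the library size of a genome-wide experiment (5×10⁷
for ATAC, 2×10⁷ for MNase/ChIP) while holding only the fragments on the
simulated chromosomes — the toy genome is a slice of a full library. This
keeps normalized counts, and hence the 30-read threshold, in the regime of
real data.

What the generator does **not** emulate: mappability and GC bias, Tn5
sequence preference and the 9-bp duplication offset, MNase digestion bias,
fragment-length/accessibility coupling beyond the two length regimes,
peak-width variation, and inter-locus contact structure. Passing the
recovery tests therefore shows the estimators invert the generator's model
class, not that they are robust to every artifact of real libraries.

## Problem sizes and numerics

Default test/acceptance scale — 5 Mb genome, 900 loci, 3 replicates, ~0.25 M
fragments per ATAC replicate — was chosen so the full suite completes in a
few minutes on one CPU while keeping per-class counts large enough that the
stochastic checks have comfortable margins. All randomness flows through
`numpy.random.default_rng` with explicit seeds; same seed, same bytes.
Degenerate inputs fail loudly: empty anchor sets, zero library sizes,
all-zero dyad matrices and shape mismatches raise instead of propagating
NaNs; an all-zero scanning comparison returns p = 1 with a warning.
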