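# Methods

`fivec` implements the analysis side of an anchored 5C (chromosome
conformation capture carbon copy) experiment: the kind of design used to ask
which parts of a 0.5–1 Mb locus physically contact a gene promoter, and
whether those contacts coincide with regulatory chromatin (DNase I
hypersensitive sites, H3K27Ac, CTCF). This note records the models,
parameter choices and numerical decisions behind each stage, and what the
synthetic validation does and does not establish.

## Coordinates and digestion

All public coordinates are 1-based with inclusive ends, the convention in
which locus boundaries are quoted in genome-browser text
(`chr4:88,560,000-89,230,000`). BED files are 0-based half-open; conversion
happens only at the file boundary and is round-trip tested. The in-silico
EcoRI digest places fragment boundaries at the top-strand nick (G^AATTC);
the 4-nt 5′ overhang is not modelled because 5C resolution is the
restriction fragment, not the base. `N` never matches a restriction site or
a primer — ambiguous sequence is treated conservatively as unmatchable.

## Primer design

One oligo per eligible restriction fragment. Forward primers read the top
strand ending at the fragment's downstream cut site; reverse primers read
the top strand starting at the upstream cut site. Stored this way, a
ligation junction is literally `forward.genomic_seq + reverse.genomic_seq`,
which keeps design and quantification consistent by construction. Oligo
targets are 30 nt and 60 °C; the length search expands/contracts ±5 nt
around the target and keeps the length whose nearest-neighbor Tm is closest
to 60 °C, breaking ties toward shorter oligos. Melting temperatures come
from the unified nearest-neighbor thermodynamic model (Allawi & SantaLucia
parameters, entropy-based monovalent-salt correction, 50 mM Na+, 25 nM of
each strand).

Fragments are excluded, with a recorded reason, when they are longer than
20 kb or shorter than 100 bp (a fragment must comfortably host a 30-mer at
each end), when the candidate oligo's dinucleotide entropy falls below half
the 4-bit maximum (low complexity — a homopolymer scores 0 bits, a
dinucleotide repeat 1 bit, random sequence ≈3.7 bits), or when any 16-mer
of the oligo occurs more than once in the supplied sequence universe
(multi-target). The entropy and k-mer screens stand in for the web-tool
quality filters of the original design software, whose exact parameters are
not public; they implement the same intent — reject repetitive and
non-unique priming sites — in an auditable form. Universal sequencing tails
(30-nt A-key 5′ of forward oligos, 23-nt P1-key 3′ of reverse oligos) are
exact string constants. 5′ phosphorylation of reverse primers is recorded
as a boolean; it is chemistry, not computation.

Two schemes are supported: *anchored* (reverse "bait" primers on the
promoter fragments, forward primers tiling everything else) and
*alternating* (orientations alternate along eligible fragments, used for
control regions; the starting orientation is configurable).

## Synthetic study and its contact model

The generator builds a locus whose ground truth every downstream stage is
checked against. Contact weights follow

    w_ij = (|mid_i − mid_j| + d0)^(−α) · β^(#boundaries crossed) · λ_ij

with defaults α = 1, d0 = 5 kb, β = 0.3 and loop enrichments λ = 8. These
are fabricated to mimic the qualitative decay, boundary dip and loop
strength of published 5C profiles; they are not estimates from any dataset.
The default geometry is a 280 kb locus of 26 EcoRI fragments (~11 kb each,
25% spacing jitter), an anchored design with 2 promoter baits and 24
forward primers, one TAD boundary at 72% of the locus, and three planted
promoter loops — two inside the promoter TAD, one across the boundary,
the hardest case for a global background model. Control regions mirror the
alternating-design controls of real studies: a small gene region (5
fragments, 2 forward/3 reverse) and a gene-desert region (26 fragments,
13/13), both with plain distance decay.

A sequencing run is one multinomial draw over all countable junctions plus
an absorbing background category standing for the non-junction material
that dominates real amplicon runs. A library's compaction factor γ scales
the read fraction of every probed region against that fixed background.
This is the construction that makes γ identifiable: in a fixed-depth run
with no background, a global scale factor cancels out of the multinomial
and no normalization could recover it. Default composition at γ = 1: study
region 30% of reads, each control region 6%, background the rest (γ values
up to ≈2.8 stay feasible). Reads are emitted 5′→3′ from the forward side as
single-end full junctions with i.i.d. substitution errors at the library's
error rate; indels and base-quality structure are not modelled. All
randomness flows through one seeded generator; identical seeds give
bit-identical FASTQ.

## Junction counting

Reads are demultiplexed against the design's (forward, reverse) pairs:
universal tails are stripped if present, the prefix must match a forward
primer and the following bases a reverse primer, each within `max_mismatch`
(default 2) substitutions. Both read orientations are scanned by default
(sequencer orientation is not assumed). A read whose best score is tied
between two pairs is discarded as ambiguous rather than assigned at random;
only forward×reverse pairs are countable, since the ligation chemistry
cannot join two primers of the same orientation. Counts conserve reads
exactly (assigned + unassigned = total, enforced by the container) and are
independent of read order.

## Normalization

Two stages, applied per library against a designated reference:

1. **Depth**: each contact's count divided by the run's total reads.
2. **Compaction**: over control-region contacts nonzero in both libraries,
   per-contact ratios sample/reference are summarized by their median
   (mean available); at least 3 shared contacts are required. The study
   data are divided by this factor (value = (raw/total)/factor), mapping
   the sample onto the reference scale; the opposite direction is available
   and the choice is recorded in the output metadata.

The median was chosen over the mean for outlier robustness; zero contacts
are excluded rather than imputed to avoid pseudocount bias in a ratio of
fractions. The two control regions are aggregated jointly, with a
per-region breakdown available as a diagnostic. The reference normalizes to
itself with factor exactly 1.

## Profiles, binning and strong-contact calling

The promoter profile of a library is, per forward fragment, the arithmetic
mean of its normalized frequency over the anchor baits (fragments seen by
only some anchors are averaged over those and flagged). Profiles are
smoothed with sliding windows — 80 kb advancing by 1/6 of the window for
display, matching how such profiles are usually drawn — with inclusive
start/exclusive end membership by fragment midpoint. A window containing no
fragments is *missing*, never zero. Fragment-length weighting is
deliberately omitted.

Strong contacts are scored against a fitted monotone distance decay:
log v = a − α·log(d + c) with α ≥ 0 and a fitted short-range offset c,
weighted by approximate per-point read mass. Two details matter in
practice and are the package's own design choices:

* **Fragment-level expectations.** The fit is done on the profile's
  fragment points, and each window's expected value is the mean of the
  fitted curve at its member points. Evaluating the curve at window centres
  instead biases sparse windows on a steep decay by tens of percent —
  pure geometry masquerading as signal.
* **Local background.** After the global fit, each point's expectation is
  shifted by the median log-residual of its nearest kept neighbours
  (default 6). This absorbs structure the single decay curve cannot carry —
  TAD insulation steps, compartment-scale offsets — while a single looping
  fragment cannot move its neighbourhood's median. Upward outliers are
  masked from the fit (and from baselines) and the curve refitted once;
  downward structure is kept, because dips are background.

Window scores are log residuals times √(window read mass), studentized by
an iterated median/MAD scale. When the caller supplies the read depth
(`count_scale` ≈ anchors × total reads), scores are in Poisson
standard-deviation units and the scale is floored at 1, so a profile that
matches the background perfectly cannot shrink the scale and turn count
noise into calls. Runs of consecutive windows at or above the z threshold
(default 3) merge into regions ranked by peak score; windows overlapping an
anchor midpoint are excluded. For calling on the synthetic study the
pipeline uses windows of 3× the median fragment size (6× step) — fine
enough that one looping fragment dominates its window; the 80 kb display
binning is too coarse for fragment-scale loops at this locus size.

Under the default study conditions (λ = 8, α = 1, β = 0.3, 10⁵ reads) the
three planted loops are recovered as the top-three ranked regions, and 20
loop-free, boundary-free simulations yield at most one called region in
total at z = 3. The false-call rate is not zero by construction — a z = 3
rule admits roughly one excursion per ~20 runs — so individual seeds can
show an occasional single call.

## Annotation

Called regions are intersected with user-supplied BED tracks. Per region
and track: total overlap in bp (inclusive interval arithmetic), distance to
the nearest feature (0 when overlapping, infinity for an empty track), a
`coincides_with_*` flag for any overlap and a `near_*` flag within a
threshold (default 10 kb, chosen because "proximity" to a CTCF site is not
quantified more precisely in common usage; it is configurable and echoed in
the report). Track scores are carried through but not thresholded. The
report lists signed TSS-relative positions in kb at 0.1 kb precision,
negative upstream, ranked by profile score.

## Reporter statistics

Per-well transfection-normalized activity is luciferase/beta-galactosidase;
a construct's fold is the ratio of its mean activity to the basal promoter
construct's (the basal construct is exactly 1 by convention). SEM is the
standard error of the construct's normalized replicate activities. The
default fold is ratio-of-means; a paired mean-of-ratios variant exists for
tables with matched replicates. Significance against the basal construct
uses Student's equal-variance unpaired t-test by default (the convention of
common commercial statistics software when "unpaired t-test" is requested),
with Welch's variant behind a flag. Two zero-variance groups with equal
means give p = 1 by convention; zero variance with unequal means is
degenerate and reported without a p-value at the table level. Note that
with n = 3 per group a mean shift of ten standard deviations still cannot
reach p < 10⁻⁴ (t = 12.25 on 4 df gives p ≈ 2.6·10⁻⁴); the headline
significance levels of such assays require the full replicate count
(n = 9).

## What the synthetic validation shows — and does not

Passing tests establish that the pipeline's arithmetic is correct (oracle
equivalence, exact ε = 0 round trips), that the normalization recovers a
planted compaction factor within a few percent at realistic depth, and that
the caller separates planted fragment-scale loops from a decay-plus-TAD
background with high margin at these read counts. They do not establish
performance on real 5C data, which additionally contains PCR duplicates,
indel-rich reads, mappability and GC biases at the fragment level, cell
population heterogeneity, and distance-decay shapes outside the single
power-law family. The generator's parameters are stated conditions, not
estimates; conclusions transfer only to the extent real data resemble
them.

## Problem sizes

Default test and validation sizes — 280 kb locus, 26 fragments, 10⁵ reads
per library, 10 seeds per recovery curve, 20 null simulations — were chosen
as the smallest sizes at which every recovery claim is comfortably out of
the noise; all are parameters, and larger runs only tighten the estimates.
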