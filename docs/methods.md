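# Methods

This note documents the models behind the synthetic-data generators, the
numerical conventions of each statistic, and the design choices made where
more than one reasonable convention exists. Everything here is what the
code does; no empirical claim is made beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Synthetic plate images

A plate is a disk filling 95% of the shorter image side (default
1024×1024 px, standing in for an 8.6 cm dish at roughly 12 px/mm), with a
uniform lawn intensity per channel (default 0.55 of the 16-bit range).
Per phenotype class, the number of plaques is drawn from
Poisson(C·V·10^−d) — the same law the titer estimator inverts — and each
plaque is a disk with lognormal radius (default log-mean 2.2, log-sd 0.25,
i.e. median ≈ 9 px ≈ 0.75 mm). A plaque multiplies the lawn by
`1 − deficit_depth` (default 0.9) in every channel its phage kills:
red-host phages kill the red channel, green-host phages the green channel,
plasmid-dependent phages both. Plaque edges taper with a radial cosine
ramp over the outer 20% of the radius — a fixed constant chosen to avoid
unrealistically crisp disks. Gaussian lawn noise (default sd 0.01 of the
dynamic range) is added after rendering, and images are quantized to
unsigned 16-bit.

Placement is uniform over the plate disk eroded by the plaque radius.
Overlaps are allowed by default (crowded plates overlap in reality, and
the truth table still records every planted plaque); setting
`min_separation_px` switches to rejection sampling of non-overlapping
disks, which is the configuration used for detection benchmarks, since
only there is a one-to-one plaque/detection correspondence well defined.

What the generator does *not* model: agar chemistry, resistant
micro-colonies regrowing inside plaques, plate illumination gradients,
camera vignetting or chromatic misregistration. Passing benchmarks on
these images therefore demonstrates the correctness of the deficit
pipeline and its thresholds, not robustness to every real-world imaging
artifact — the relative-deficit design (see below) is what carries over.

## Plate analysis

Exposure is linearly rescaled per channel so the `p_lo`/`p_hi` percentiles
(defaults 0.5/99.5) map to 0/1; constant images map to zero. The display
merge puts the red fluorescence channel in red and the green channel in
blue, so two-host lawn regions appear magenta and plaques where both hosts
die appear black.

The lawn background is estimated per channel by grayscale morphological
closing with a disk of radius `r_bg` (default 48 px, about 3× the 99th
percentile of the default plaque radius; the closing uses scikit-image's
sequence-decomposed disk footprint for speed). The per-pixel relative
deficit `(background − intensity)/background` is used for both detection
and classification: because it is a ratio, uneven lawns and global
exposure changes cancel, which the tests verify as invariance under
global intensity scaling. Candidate pixels exceed the deficit threshold
`θ_d` (default 0.4) in at least one channel, restricted to the plate disk
(largest bright Otsu component of the channel sum, holes filled).
Components are 8-connected, and regions under `a_min = 20` px are
discarded. Touching plaques count as one region by default; a
distance-transform watershed split is available behind
`VisionParams(watershed_split=True)`. A region's class follows its mean
per-channel deficits: both ≥ θ_d → plasmid-dependent; red only → phage of
the red-labelled host; green only → phage of the green host; neither →
artifact (reported separately, never added to phage counts).

## Titer estimation

Counts are pooled across plates and dilutions as a Poisson MLE — summed
counts over summed effective volumes Σ Vᵢ·10^−dᵢ — rather than averaging
per-plate titers, which would overweight low-count plates. The confidence
interval is the exact Garwood construction on the pooled count
(χ²_{α/2, 2c}/2 to χ²_{1−α/2, 2c+2}/2, α default 0.05), divided by the
effective volume; it is conservative, with empirical coverage ≈ 95–98%
across the rates exercised. A countable-range filter (default 3–300
plaques, overridable) drops plates outside the reliable counting window;
if no plate qualifies, all are used and the estimate is flagged. The
abundance table reports both the pooled interval and the replicate
standard deviation, since either error representation may be wanted.

## Growth curves and the liquid assay score

The simulated plate-reader format is 10 h at 5-min intervals (121
timepoints), with every condition in triplicate and each plate carrying
phage-free controls per host and shared cell-free blanks. Controls follow
a logistic `K·OD₀·e^{rt}/(K + OD₀(e^{rt}−1))` above a blank baseline
(defaults OD₀ 0.05, K 1.0, r 0.015/min, blank 0.08). An infected well's
expectation interpolates linearly between the control trajectory and a
full-lysis trajectory — logistic until the lysis onset `t_lyse` (default
120 min), then exponential decay toward the blank at 0.02/min — with the
planted inhibition η ∈ [0,1] as the mixing weight. No kinetic claim is
intended; any monotone family would do, and this one makes the liquid
assay score exactly 100 at η = 0 and strictly decreasing in η with noise
off, which is what the calibration tests assert.

Scoring subtracts the per-timepoint mean of the plate's cell-free blanks
from every curve, floors negatives at zero, and integrates by the
trapezoid rule over the full window, reported in OD·hours. The score is
100·mean(infected AUC)/mean(control AUC) using the host's same-plate
controls; scores above 100 are reported as-is. Blank subtraction is a
deliberate choice worth flagging: it rescales numerator and denominator
unequally except in the identity case, so scores from pipelines that skip
it are not numerically interchangeable with ours away from 100. Pairs
with no data stay masked (NaN), never 0 — a 0 means complete suppression.
Matrix ordering by Newick trees (dendropy, depth-first leaf order as
written) only permutes rows/columns; labels missing from a tree are
appended in input order and flagged.

## Genome collections and diversity statistics

The generator plants clusters under a star-within-star genealogy: a random
reference (default 15 000 bp tiled by 31 contiguous genes), one ancestor
per cluster mutated from the reference, and leaves mutated from their
ancestor. Substitutions only — no indels — so sequences stay equal-length
and gene synteny is conserved by construction. Identity targets convert
to branch substitution probabilities: `mu_within = (1 − within/100)/2` per
leaf branch and `mu_between` set so cross-cluster pairs reach the between
target (defaults 98% within, 90% between, bracketing the 95% species
cut-off with margin). This genealogy gives direct analytic control of the
identity structure; it is not a coalescent, carries no recombination, and
the slight upward bias from coincident/back mutations at high rates is
accepted (rates are validated to stay ≤ 0.25/site). Per-gene rate
multipliers create SNP hotspots.

Statistics conventions, chosen once and applied everywhere:

* **Comparable positions.** A position enters pairwise identity only if
  both sequences carry A/C/G/T; gaps and N are excluded (pairwise
  deletion, no imputation). Identity is undefined (NaN) with zero
  comparable positions.
* **Species clustering.** Single linkage on pairs with identity ≥ θ
  (default 95%), computed as connected components; a pair at exactly the
  threshold is linked, because the demarcation is *strictly below* the
  cut-off. Complete linkage is available behind a flag for
  every-pair-must-qualify semantics.
* **Nucleotide diversity.** Site π = Σ_{a<b} cₐc_b / C(m,2) over allele
  counts c at coverage m (isolates with an unambiguous base); sites with
  m < 2 contribute 0 rather than being dropped. Window π divides the sum
  of site π by the window *span* (default 100 bp; a short final window by
  its actual span), not by the covered-site count — so for two gap-free
  sequences, window π × span sums exactly to the pairwise mismatch count,
  an identity the tests assert. Alignment columns where the reference is
  gapped are dropped from the coordinate map. Per-gene π divides by gene
  length, strand-independent.
* **Synteny.** An isolate passes iff its gene list equals the reference
  order exactly; violations are itemized as missing/extra genes and, for
  shared genes, the minimal displaced set (complement of a longest
  increasing subsequence against reference ranks).
* **Coordinates.** 0-based half-open internally; GFF3 is read and written
  1-based inclusive; FASTA reference record id is `REF` by default.

## Problem sizes and reproducibility

Every generator takes an explicit seed and is bitwise reproducible.
Benchmark sizes were chosen as comfortable desk-scale defaults: detection
benchmarks use 1024-px plates with ~150 plaques per class (20 plates in
the test suite, 12 in the acceptance script); titer coverage uses 100
simulated dilution-series experiments of 27 plates each plus 1000-draw
interval-coverage checks; diversity oracles run on collections up to 6
sequences × 500 bp against brute-force pair counting; species recovery
uses 51 genomes in 12 clusters of realistic size spread. The acceptance
script derives all sub-seeds from its `--seed` argument.

## Known limitations

Plaque morphology beyond area (size/turbidity phenotypes) is out of scope,
as are image registration across plates, growth-parameter fitting (lag and
rate estimation), alignment and variant calling from reads, phylogeny
inference (trees are consumed as Newick only), and recombination or indel
variation in the genome model. The exposure-rescale percentiles stand in
for camera exposure settings and are not calibrated to any particular
imaging hardware.
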