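# Methods

`loopscape` implements a chromatin-loop integration analysis for
Micro-C-like contact data: simulation of binned contact maps with planted
domains and loops, TAD and loop calling, promoter-capture interaction
scoring, regulatory-element classification, loop-category annotation,
sequencing-depth saturation, and in-loop vs not-in-loop signal profiling.
This note documents the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Coordinates and containers

All coordinates are 0-based, half-open (BED convention); overlap means at
least one shared base. A contact map is a symmetric intrachromosomal count
matrix stored as its upper triangle (diagonal included); one stored entry is
one contact event, so the stored sum is the map's depth. Trans-chromosomal
contacts are out of scope throughout.

## Synthetic data model

The generator produces every input the analysis consumes, on a scaled-down
genome (default: one 20 Mb chromosome) chosen so that simulations preserve
the statistical structure of deep Micro-C data while running in seconds.

**Contacts.** The expected count at genomic distance *d* is proportional to
`(d + binsize)^-α` with decay exponent α = 1 by default; the `+ binsize`
offset removes the *d* = 0 singularity and keeps the diagonal defined.
Pixels with both bins inside a planted domain are multiplied by a TAD fold
(default 3); the pixel at a planted loop's anchor pair is multiplied by the
loop fold (default 6). Folds multiply the expectation (log-additive with the
decay), matching observed/expected semantics. The expectation is scaled so
the upper-triangle total equals the configured depth (default 5 × 10⁶ for
20 Mb at 10 kb bins, ≈ 10 counts/pixel at mid-range loop distances), then
counts are drawn Poisson. No systematic bin bias is simulated, which is why
no ICE/KR balancing is implemented; on real data, O/E without balancing is a
documented limitation.

**Domains.** Planted TADs partition the chromosome into adjacent blocks
with gamma-distributed sizes (shape 4) around a 450 kb mean, snapped to
50 kb bin edges so that ground-truth boundaries are well defined at the
analysis resolution.

**Annotation.** TSS positions are uniform per chromosome with log-normal
FPKM replicates (default ln-scale μ = 0, σ = 1.5, three replicates), so
expression spans the 0.5 FPKM activity threshold. Peak widths are normal
per mark (H3K27ac ≈ 1.2 kb, CTCF ≈ 350 bp, H3K27me3/H3K9me3 ≈ 1.5 kb, NDRs
≈ 600 bp — active elements under 2 kb, NDRs under 1 kb). A configurable
fraction of peaks is rejection-sampled to lie > 2 kb from every TSS so the
enhancer/insulator exclusion rules are exercised.

**Planted loops.** Each loop draws a category from the configured weight
table (defaults rank insulator–insulator first, then promoter–insulator,
promoter–promoter, …), a separation from a log-normal law (median 350 kb),
and anchors on element pairs of that category. Two generator rules keep the
ground truth well defined: the category is drawn once per loop and held
fixed across placement retries (redrawing on failure would bias frequencies
toward categories with larger element pools), and only elements that
annotate back to their own label under the ±2 kb fuzzy window are eligible
as anchors (an anchor that a higher-priority neighbor would re-label has no
meaningful planted category).

**Signal tracks.** MNase, accessibility (%) and methylation (%) tracks are
generated piecewise-constant on a 10 bp grid in a ±2.6 kb footprint around
each element center: a Gaussian nucleosome-depleted dip plus a damped cosine
(period 190 bp by default — a configurable choice, not a measured constant)
for MNase; a central bump for accessibility; a central trough for
methylation; Gaussian noise on top. In-loop elements get a deeper dip,
stronger phasing amplitude, +20 accessibility points and −15 methylation
points by default. No quantitative effect sizes are published for these
contrasts; the defaults are free parameters chosen to be visually clear yet
noisy, and the recovery tests check signs and approximate magnitudes, not
exact values. Bases outside all footprints are missing (NaN), matching
coverage-track semantics (bedGraph gaps are missing, not zero).

**Randomness.** One global integer seed; every operation draws from a
sub-stream keyed by (seed, CRC32 of the operation name), so call order does
not affect results and fixed seeds give byte-identical outputs.

## TAD calling

A TopDom-style analogue (not a clone — the published tool's pseudo-counts
and gap handling are tool-internal): the bin signal at boundary *i* is the
mean count of the w×w block spanning bins (i−w…i−1)×(i…i+w−1), default
w = 5 at 50 kb. Candidate boundaries are strict local minima after plateau
merging (ties resolve to the leftmost bin, for deterministic output);
chromosome-end windows are truncated, never wrapped, and end bins with no
two-sided evidence are not candidates. Each candidate is tested by a
one-sided Mann-Whitney rank-sum comparison of cross-boundary pixels against
the within-side upper-triangle pixels of the two flanking w-blocks; kept at
p < 0.05. Domains shorter than 2 bins are dropped. TAD-set comparison calls
a domain shared when both boundaries match a domain in the other set within
a bin tolerance, reported in both directions.

## Loop calling

A simplified HiCCUPS-style donut test. For each candidate pixel within the
distance bounds, four neighborhoods are formed in pixel offsets (radius p
peak, w donut; defaults p = 1, w = 5): donut annulus excluding the center
cross, lower-left quadrant, horizontal stripe, vertical stripe. The local
expectation is the **maximum** over neighborhoods of (neighborhood
observed/expected ratio) × (pixel distance expectation) — conservative: a
pixel must beat its worst-case local background. The pixel model is Poisson
(simulated counts are Poisson; this keeps the null oracle closed-form —
negative binomial would be the real-data choice). P-values are
Benjamini-Hochberg corrected across all candidates of one map at one
resolution (resolutions are independent analyses), kept at q < 0.20.
Adjacent significant pixels merge by 8-connectivity; the lowest-q pixel
represents the cluster and always lies inside its bounding box.

The capture-style score restricts candidates to pixels with at least one
anchor bin overlapping a bait (promoter window) and replaces the FDR step
with a fixed score = −log10(p) > 5 cutoff, mirroring promoter-capture
interaction calling; each kept interaction carries its bait id and clusters
merge as above.

Loop distances are classified into the six bins < 200 kb, 200–400 kb,
400–600 kb, 600–800 kb, 800 kb–1 Mb, > 1 Mb, left-closed/right-open (a
400,000 bp loop is "400–600 kb"; exactly 1 Mb is "> 1 Mb").

## Element classification

Exclusion hierarchy, applied in order: active promoters are TSS ±2 kb
windows with mean FPKM strictly above 0.5 (the activity threshold is a
strict inequality: exactly 0.5 is excluded); enhancers are H3K27ac peaks with zero overlap with any TSS
±2 kb window ("> 2 kb from TSS" interpreted as an interval test against the
windows, not a midpoint distance, for consistency with the windowed
promoter definition); insulators are CTCF peaks clear of TSS windows and of
enhancers; NDRs-without-features, repressed (H3K27me3) and heterochromatin
(H3K9me3) regions are the corresponding peaks clear of everything above
them. Profile centers: TSS for promoters; midpoint of the widest
overlapping NDR for enhancers; midpoint of the leftmost overlapping CTCF
motif for insulators; own midpoint for NDRs; fallbacks to the peak midpoint
are flagged.

## Anchor annotation and loop categories

A loop anchor is expanded by a resolution-keyed fuzzy window (±2 kb at 1 kb
resolution, ±10 kb at 5 kb; 2× the resolution otherwise) and annotated with
the highest-priority intersecting element label
(promoter > enhancer > insulator > NDR > repressed > heterochromatin >
none). The window expands the anchor, not the element: the expansion exists
to tolerate interactions one bin away from the element. Ties between
same-priority elements break to the larger overlap, then leftmost —
deterministic and order-independent. A loop category is the unordered label
pair canonicalized by priority; 7 labels give exactly C(7,2) + 7 = 28
categories. Shared-loop analysis uses the same fuzzy join per anchor
(anchor1↔anchor1, anchor2↔anchor2 after canonical ordering); because one
loop can match several in the other set, shared counts are direction-
dependent by design.

## Profiles and group comparisons

Signal profiles aggregate a track in 10 bp steps over ±2 kb around element
centers (plot-window defaults; the published figures do not state exact
parameters), with promoter rows strand-flipped so downstream is positive
and missing bases excluded from window means. Group comparisons reduce each
element to the mean signal over a central ±250 bp summary window (the
tested "level"; the window size is this package's choice) and apply a
two-sided Student's t-test, with equal-size resampling (10 seeded draws of
a fixed n per element class and group) available to control group-size
imbalance. Nucleosome phasing is scored as the lag-190 bp autocovariance of
the linearly detrended flank signal (|offset| ≥ 300 bp, excluding the
central dip); a pure cosine of amplitude A scores ≈ A²/2, white noise ≈ 0.
The published phasing comparison is visual with a single p-value and no
formula; this score is the package's operationalization.

## Depth saturation

Titration tiers are **nested** binomial thinnings (tier k is a sub-draw of
tier k+1), mirroring a titration that combines sequencing libraries
cumulatively; independent per-tier thinning would add spurious
tier-to-tier jitter. Depth is measured in contact counts as a proxy for
read pairs (the valid-pair-to-contact conversion of real libraries is out
of scope; stated on every output). In capture mode the recorded depth is
the captured depth — counts in pixels touching a bait — because a capture
library only sequences bait-overlapping fragments; this is what makes
bait-restricted calling reach its plateau with far fewer sequenced reads
than genome-wide calling on the same material. The plateau is the first
tier whose relative gain to the next is below ε = 5% — saturation needs an
operational rule, and this one is the package's.

Two subtleties the validation experiments respect. Saturation runs on
loops-only maps: with TAD blocks present, domain corner dots keep crossing
the significance threshold as depth grows and the genome-wide count curve
never flattens. And monotonicity is checked on *planted-loop recovery*
counts, not total calls: a low-depth false positive's relative excess
regresses to the mean as nested depth grows, so total counts provably
wiggle by a few calls around the plateau even for a correct caller.

## Pipeline

`run_pipeline` executes simulate → classify → tads → call → capture →
annotate → profile → titrate, each stage a pure function of files in the
output directory, single-process, any subset runnable. It writes a JSON
manifest with the SHA-256 of every produced file plus the seed and
parameters; identical config and seed reproduce identical checksums. The
`loopscape` CLI is a thin wrapper (subcommands per stage plus `run`; global
`--config/--outdir/--seed`).

## Validation experiment sizes

The `loopscape.validation` module fixes the benchmark conditions: loop
recovery on a 6 Mb chromosome at 10 kb bins, 35 fold-6 loops, 2.5 M
contacts, ±1-bin matching; category ranking with 1,500 planted loops on a
20 Mb scene annotated at the ±2 kb window; null FDR on 4 Mb decay-only
maps; TAD recovery on 20 Mb at 50 kb bins, fold 3, w = 5, 0.8 M contacts
(≈ 280 counts/px at the first off-diagonal); saturation on a 6 M-contact
loops-only map over 6 nested tiers; profile effects on 4 Mb scenes with
random in-loop assignment. These problem sizes are the package's chosen
study conditions — small enough to iterate on, large enough that every
recovery statistic is far from its decision boundary.

## Known limitations

* Poisson (not negative-binomial) pixel model and no matrix balancing:
  appropriate for the simulated data; real Micro-C would need both.
* No cross-resolution loop merging, no structural-variant-aware
  ("neoloop") calling, no trans contacts, no nested/hierarchical domains
  or compartments.
* Passing recovery tests on synthetic data shows the implementation is
  internally consistent with its own generative model; it does not show
  calibration on real chromatin, where overdispersion, bin bias and
  assay-specific artifacts all matter.
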