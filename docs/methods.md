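# Methods

This note documents the models, numerical choices and known limitations of
`nucleostates`, in the order data flows through the pipeline.

## Dyad calling

Fragment midpoints per chromosome are binned at 1 bp and smoothed with a
Gaussian kernel of bandwidth `w = 30` bp (the default smoothing scale for
nucleosome-stringency profiles; exposed as `bandwidth`).  Local maxima of the
smoothed density are dyads; maxima closer than 120 bp — less than a
nucleosomal repeat — are merged keeping the higher peak.  Footprints run
between the flanking density minima, clipped to dyad ± 100 bp, so adjacent
footprints meet at the shared minimum and never overlap.  The peak area `S`
is the density integral over the footprint (≈ the midpoint count), the width
`W` the footprint length, and the degree of positioning (DoP) the ratio of
midpoints within ±20 bp of the dyad to those within ±73 bp (a core-particle
half-width), 0 when the denominator is empty.  The caller is intentionally a
minimal smoothing/local-maximum scheme: the downstream model needs only
(dyad, S, W, DoP), so peak-shape classification found in full positioning
tools is out of scope here.  On any ≤10 kb input the caller agrees with a
brute-force 1-bp-grid kernel-density argmax to ±1 bp (tested).

## Grouping (λ, β, γ)

Per nucleosome, `λ = S/W + ω(μ − d)` with `ω = 0.005` by default, chosen so
that for a typical `S/W ≈ 2` and a spacing deviation `|μ − d| ≈ 30` bp the
two terms are of comparable order; `μ` is the mean inter-dyad distance in a
centred 10-kb window, **restricted to distances in 150–350 bp** — without
that restriction inter-array deserts inflate `μ` and the ω-term swamps
`S/W`.  For the last nucleosome of a chromosome, and for any nucleosome whose
next-neighbour distance exceeds 350 bp (an inter-array gap, not a spacing),
`d` is set to `μ` so the ω-term vanishes.  `β = Σ_k w_k a^k b` with unit mark
weights by default; `a^k` and `b` are footprint read counts scaled to
reads-per-million.  When no mark profile is supplied β ≡ 1 and grouping runs
on λ alone.

The scan merges nucleosome `i+1` into the running group while
`|γ| = |(λ_i β_i − λ_{i+1} β_{i+1}) / Σ_{n≤i} λ_n β_n| < 0.10` and
`d ≤ 350` bp.  γ is signed; the merge test uses its absolute value.  If the
running product sum is zero, a zero-product candidate merges (identical
degenerate profiles) and a nonzero one splits; the standalone
`similarity_ratio` still raises on a zero denominator.

## Regularity

For a group spanning ≥2 nucleosomes, the 1-bp midpoint-count signal over the
span (±200 bp margin) is mean-detrended and passed to Welch's method
(Hann window, `nperseg = 512`, 50% overlap).  The score is the mean PSD over
the band `1/μ_group ± 10%` divided by the median PSD over all nonzero
frequencies.  The band is narrower than the Welch frequency grid
(Δf = 1/512 ≈ 0.002 vs band width ≈ 0.001 at μ ≈ 210), so band power is read
off the PSD by linear interpolation at 50 points across the band — this is
why an interpolating step is part of the definition, not a cosmetic choice.
White noise scores ≈1 by construction; scores decrease monotonically with
dyad jitter (tested).  Single-nucleosome groups score 0.  Absolute published
regularity values are not reproducible because their normalisation is
under-specified; only orderings (S5 highest, S8 lowest) are asserted.

## State classification

Feature vector per group: member count, mean intra-group spacing (singleton
groups take the cohort mean), regularity, mean DoP, promoter/proximal/distal
member fractions (strand-aware windows: promoter TSS ± 1 kb, proximal 1–5 kb
upstream, distal 5–50 kb upstream; nearest TSS wins; half-open boundaries in
coordinates), and the eight mark signals.  Features are z-scored
(zero-variance features dropped with a warning) and clustered with K-means
(k-means++, K = 9 fixed to mirror the nine published states, 50 restarts,
fixed seed; an inertia sweep over K is available but no automatic selection
is made).  Clusters are mapped one-to-one onto S1–S9 by solving the
assignment problem (Hungarian algorithm) between cluster centroids and a
rule table distilled from the states' published descriptions, with both
sides z-scored across the nine rows so units cancel.

## Condition switching

Groups from two conditions are matched per chromosome by span overlap.  The
match requires overlap ≥50% of the **shorter** span and greedily takes the
highest such containment fraction, each target group used once (ties to the
leftmost source span).  Measuring against the shorter span rather than the
source span is deliberate: a state switch that shrinks an array in place
(a 20-nucleosome S4 replaced by a 3-nucleosome S3 at the same anchor) has
small source-span overlap and would otherwise be dropped — exactly the
switched regions the transition table must count.  The threshold and the
reported source-span overlap fraction are both exposed.  A source region
whose span contains no target-condition nucleosome is NFR (operational
definition).  The transition table reports counts, row percentages,
per-state switched fractions `100·(1 − stay/row total)` and state-count
ratios `100·(column sum / row sum)`, all region-weighted.  RAS flags are set
membership: S4→{S2,S3,S7,NFR} (RAS1), S3→{S2,S6,NFR} (RAS2), exclusive per
region.  Gene association uses the span midpoint with priority gene body >
promoter (1 kb upstream) > proximal (1–5 kb) > distal (5–50 kb); within a
tier the nearest TSS wins, exact ties break to the lexicographically smaller
gene id.  Note the 1-kb *upstream-only* promoter of the assignment priority
differs from the ±1-kb promoter of the annotation windows; both definitions
are implemented separately on purpose.

## Border integration

A border pair is represented by its midpoint `(left + right) // 2`; the pair
generator centres pairs so this floor-division midpoint recovers the true
centre exactly.  Pairs are assigned to the nearest dyad within 100 bp
(≈ half-footprint plus margin); the signed offset is midpoint − dyad and the
edge flag is `50 ≤ |offset| ≤ 60` bp.  Border *calling* is not reimplemented
— borders are ingested at 1-bp resolution.  Whether "edge" should be
measured from the dyad or the footprint boundary is ambiguous; the dyad
offset with a 50–60 bp window is used.

## Synthetic data generator

The generator encodes the study conditions the pipeline is validated
against.  Defaults, with the reasoning for free choices:

* **Layout.** Regions occupy fixed 26-kb slots, one array and one gene per
  region.  The gene is placed at a class-determined offset from the array
  centre (promoter 0, proximal 3.2–4.5 kb, distal 9–20 kb, upstream side by
  strand); the pitch guarantees the nearest upstream-covering TSS of every
  array is its own gene, making region-class ground truth exact.  Regions
  are therefore independent sampling units; real chromatin has contiguous
  arrays and overlapping gene contexts, so passing tests validate the
  estimators, not genome-scale segmentation behaviour.
* **Spacing.** The genome-wide inter-dyad spacing mixture is
  0.65·N(187, 5²) + 0.35·(150 + lognormal with mode 37, σ = 0.45),
  truncated to [150, 350] bp: only the 187-bp mode is observation-anchored,
  the skewed-tail shape is a modelling default.  Each array draws one
  repeat length (NRL) — from its state's normal (S2 180.43 ± 6, S4
  210.64 ± 7, ...) or from the global mixture — and members jitter around it
  with a small sd (2–6 bp; 15 bp for fuzzy S8).  An array-level NRL with
  tight member jitter reflects phased arrays having a characteristic repeat;
  fully independent per-linker draws would make the ω-term noise fragment
  arrays under the 10% γ rule.
* **Occupancy.** ~300 midpoints per nucleosome (deep, saturated coverage;
  `S/W ≈ 2`), with a lognormal per-array amplitude (σ = 0.15) and 1%
  within-array jitter: occupancy is coherent along an array.  The nucleosome
  table carries *true* peak areas; sampling noise lives in the emitted
  midpoints (Gaussian positional jitter, sd 14–45 bp by state), which is
  what the dyad caller consumes.
* **Marks.** Each array draws a lognormal intensity scalar multiplying its
  state's mark-intensity profile; a mark is "carried" when its intensity
  exceeds a detection level of 0.6622.  For S4 (repressive profile scaled by
  a σ = 0.6 lognormal) this threshold yields a 75.4% carrier fraction
  exactly.  A continuous intensity was chosen over per-mark Bernoulli
  presence because presence/absence makes each state's feature cloud a
  mixture of 2^k mark combinations, which no one-to-one K=9 clustering can
  resolve; the continuous model keeps clouds unimodal while preserving the
  carrier statistic.
* **Transitions.** The Veh→DHT matrix fixes S4: stay 0.279, →S3 0.454
  (read as a fraction of *all* Veh S4; the conditional reading is available
  as `s4_to_s3_conditional`), and S3→S2 0.423.  The S2 column of the six
  unconstrained donor rows is a single rate solved analytically at
  construction so the expected DHT/Veh S2 count ratio is 2.024 under the
  default priors.  NFR destinations emit no nucleosomes.
* **Borders.** 42.1% (Veh) / 36.2% (DHT) of pairs are centred on
  nucleosomes; on S3/S4 nucleosomes the |dyad offset| falls in 50–60 bp with
  probability 0.85 (remainder, and all other states, uniform within 45 bp of
  the dyad); off-nucleosome pairs land >130 bp from any dyad.  Gaps are
  8 + Poisson(5.5), giving a 13-bp modal gap.
* **Determinism.** One integer seed; every sub-generator derives child
  streams from `numpy` `SeedSequence` spawning in a fixed order, so equal
  config+seed reproduces outputs byte for byte.

## Problem sizes

Validation uses desk-scale runs chosen as the smallest sizes at which
binomial/sampling error is well inside each tolerance: ~53,000 dyads for the
spacing mode (±2 bp), 5,000 regions per donor state for transition
percentages (±1.5 points), 15,000 mixed-prior regions for the S2 count ratio
(±5 points), 40,000 border pairs (≥5,000 S3/S4-assigned), and 200 groups per
state (~1,800 regions) for classification recovery.  Genome-scale absolute
quantities (total nucleosome counts, genome coverage, absolute regularity
values, real-data state counts) are out of scope.

## Known limitations

* The γ rule is sensitive to per-nucleosome signal noise by construction;
  on shallow or incoherent data it produces small groups.  This is a
  property of the model, not of the implementation.
* Cluster→state naming assumes the cohort actually contains all nine states;
  on data missing a state the Hungarian matching will still hand out every
  label.
* The mark model emits array-coherent signal; per-nucleosome mark
  heterogeneity within an array is not simulated.
* MNase digestion bias, fragment-length structure and raw sequence content
  are not modelled (the generator emits midpoints, not reads).
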