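# Methods

This note documents the models, parameter choices and numerical
decisions behind `cremap`, and what the synthetic experiments do and do
not demonstrate about real data.

## Experimental design being modelled

Two strains (wild type, regulator knockout) at two chemostat dilution
rates (0.07 h⁻¹ repressing, 0.025 h⁻¹ derepressing) yield four
pairwise two-colour comparisons:

| id | numerator | denominator | reads out |
|----|-----------|-------------|-----------|
| c1 | wt, low D | wt, high D | growth-rate effect, wild type |
| c2 | Δ, low D  | Δ, high D  | growth-rate effect, knockout |
| c3 | Δ, high D | wt, high D | regulator effect at high growth rate |
| c4 | Δ, low D  | wt, low D  | regulator effect at low growth rate |

Each comparison is hybridised twice with dyes exchanged (dye swap), so
the raw log-ratio sign flips between replicates; the design table makes
the orientation explicit rather than hard-coding it.

## Synthetic data generator

Spot intensities are log-normal with a common spot effect: the channel
geometric mean is 2^A with A ~ N(10, 1.5), and the two channels are
2^(A ± M/2) where M = orientation·(true log₂ + biological effect) +
technical noise. Two noise scales matter:

* `noise_sd` (default 0.2 log₂ units) — independent per spot; chosen as
  a typical residual spot-level scatter for two-colour arrays.
* `bio_sd` (default 0.25 log₂ units) — drawn once per gene per
  biological replicate and shared by all of that gene's probes. Without
  it, transcript-level profiles are implausibly clean (probe averaging
  shrinks spot noise by √7), and threshold-based steps such as the
  template R\* behave unlike they do on real data.

"Not found" features get intensities from 2^N(6, 0.5), well below the
unflagged distribution, so the background threshold (mean + 2 SD of the
pooled flagged channel means) separates the populations. Saturation is
simulated by pushing a small fraction of spots past the 16-bit scanner
ceiling (65535) and clipping; the preprocessing stage re-identifies
them as any channel at or above the ceiling, since "saturating" has no
sharper operational definition upstream.

Regulated genes are planted from nine behaviour-category centroids over
(c1..c4), scaled to ±3 log₂ units (comfortably past the selection cut
of 2): A/B growth-rate-only (up/down at low D), C up in the knockout at
both rates, E/F up/down in the knockout at high rate, D down in the
knockout at low rate, G/H the regulator counteracting an induction at
high/low rate, X a heterogeneous leftover profile. Default cluster
sizes are the published ones (A:19 … X:17; 250 of 1000 genes), so the
demonstration run operates at the study's own proportions.

Promoters are i.i.d. sequences at a configurable GC fraction (default
0.5) with motif instances planted at non-overlapping uniform positions;
planted counts (not incidental background matches) are recorded, so
tests either use `>=` comparisons or set GC = 0 so that an S-containing
pattern cannot occur by chance and counts match exactly. Dyad plantings
realise first motif + uniform spacer (0..max gap) + second motif as one
block. Annotations cover a configurable fraction of genes (default
4977/9129, the annotated fraction of the modelled genome) with 1–3
uniform categories, plus one category planted at elevated rate in a
chosen cluster.

What the generator does **not** emulate: print-tip/block spatial
artifacts, scanner optics, sequence-specific dye bias, correlated
promoter composition (real promoters are not i.i.d.), or annotation
structure (GO graphs are flat term sets here). Passing tests therefore
demonstrate algorithmic correctness and calibration under the stated
noise model, not robustness to those real-data pathologies.

## Preprocessing decisions

* "Raw mean intensities above background" is read as **both** channels
  above the threshold (a ratio needs signal in both); an
  "either-channel" switch is provided.
* The SD of a single not-found value is defined as 0; no not-found
  features at all is an error, not a silent zero threshold.
* Loess: span 0.3, tricube weights, 3 robustness iterations
  (statsmodels `lowess`), fitted to M vs A over all retained spots of
  one hybridisation ("global"); residuals are the normalised ratios.
  No background subtraction anywhere. Fewer than 10 retained spots is
  an error.
* Aggregation is an unweighted mean over a transcript's detectable
  in-coding matching-strand probes; transcripts with < 2 such probes
  are dropped. Unknown probe ids are warned about and ignored.

The loess residual operation is exactly antisymmetric under a channel
swap (every internal quantity either negates or is sign-invariant), so
dye-swap antisymmetry holds to machine precision — tested, not assumed.

## Variance moderation

Per comparison, each transcript's replicate ratios give an OLS mean and
sample variance s² with d = n−1 degrees of freedom. The prior (d₀, s₀²)
is estimated by matching the first two moments of log s² under the
scaled-F model, with the prior degrees of freedom obtained by Newton
inversion of the trigamma function; when the observed spread of log s²
does not exceed pure chi-square sampling, d₀ = ∞ and all variances pool
to s₀². Limits are tested (d₀ → 0 recovers the ordinary t; d₀ → ∞
pools), and the whole path is cross-checked against the Bioconductor
reference implementation on a fixture to ~1e-10. With 2 replicates
(d = 1) moderation is what makes the test usable at all.

Degenerate cases: a transcript with all-zero replicate ratios scores
t = 0, p = 1; if nearly all variances are zero (noise-free simulations)
the prior fit falls back to pooling.

## Cluster cascade decisions

* Template groups are user input (a curator's hand-sorted behaviour
  groups). The demonstration pipeline emulates curation by taking half
  of each planted cluster; R\* is then the minimum seed correlation,
  i.e. the loosest threshold that still retrieves the whole curated
  group.
* Retrieval uses absolute correlation by default (signed mode
  available). A gene retrieved by several templates goes to the one
  with the highest signed correlation, falling back to highest |r|
  when only anticorrelated matches exist — this keeps mutually opposed
  categories (up vs down) apart without extra parameters.
* CAST: affinity is the mean Pearson correlation to current members;
  ADD inserts the highest-affinity qualifying outsider, REMOVE expels
  the lowest-affinity member below threshold; ties break to the
  lexicographically smallest gene id and the opening gene is the one
  with the highest total similarity — making the partition independent
  of input order. Zero-variance profiles have undefined correlation and
  are given zero affinity.
* A CAST cluster merges into a template group when its mean profile's
  correlation exceeds that group's R\*; unmerged clusters become X.
* Hierarchical splitting: scipy average linkage on Euclidean distances,
  cut at the root's two children; genes are sorted lexicographically
  first so linkage tie-breaking is deterministic. Groups of one are
  returned unsplit with a warning.

## Promoter analysis decisions

* Scanning is greedy left-to-right with consumption ("prevent
  overlapping matches"): since all matches of one pattern have equal
  length, the greedy set is maximum-cardinality, so planted
  non-overlapping instances are never undercounted. `N` in a sequence
  matches nothing. Only the given strand is scanned; reverse-strand
  sites are obtained by scanning the reverse-complement pattern
  (CYCCRS for SYGGRG), as the enrichment table does.
* Dyad gap is end-of-first to start-of-second, inclusive of 0 (sites
  may abut but not overlap); a start-to-start anchor is selectable.
  Every qualifying ordered (i, j) combination counts once.
* Enrichment is (cluster mean / genome mean − 1)·100, the only reading
  consistent with "normalised to the genome average"; significance is
  Welch's two-sided t of cluster counts vs genome counts, with the
  cluster included in the genome background by default (switchable).
  Stars: p < 0.1 (\*), p < 0.05 (\*\*).
* Discovery scores each word by −log₁₀ of the Bonferroni-scaled
  binomial upper tail of its per-promoter presence count in the
  cluster, against the genome-wide presence probability (clipped away
  from 0/1 by half a count). The Bonferroni scaling (an E-value-style
  significance index) keeps the maximum control score near 0–1, which
  is what makes a fixed "+0.5 above control max" margin meaningful;
  with raw −log₁₀ p the control max would be driven by multiplicity
  alone. Controls are three random same-size gene sets drawn with a
  recorded seed.
* Promoter retrieval takes the 1000 bases 5' of the start (plus strand)
  or the reverse complement of the 1000 bases 3' of the end (minus
  strand), truncating with a warning at contig edges; upstream ORFs are
  not clipped (both the clipped and unclipped readings of the original
  tool's option are defensible; unclipped is the default and the other
  is a matter of preparing the input window differently).

## Category enrichment decisions

Upper-tail hypergeometric p per category present in the cluster
(k ≥ 1); categories absent from the cluster are not tested, which also
lightens the BH burden in GO mode. The universe defaults to the
annotated genes (mirroring an analysis of "the annotated subset among
regulated genes"); a whole-genome universe is a constructor argument.

## Problem sizes and determinism

The shipped test suite and the acceptance script use 150–1000 genes,
5–7 probes per gene and 2000-gene null calibrations; these sizes give
stable statistics (Monte-Carlo SD of the calibrated rejection rates
≈ 0.002–0.005) while keeping a full run in seconds. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
identical config + seed reproduces byte-identical output files.

## Known limitations

* The published gene lists and enrichment table derive from the real
  hybridisations and genome assembly; at desk scale the package
  reproduces the printed accounting arithmetic and its own planted
  truths, not those lists. The genome-wide density computation is
  implemented and tested for internal consistency, but the printed
  genome averages (e.g. 4.13 SYGGRG sites per promoter) depend on the
  assembly/annotation version and are not asserted.
* Welch's t on per-gene site counts is the study's significance
  convention; counts are discrete and right-skewed, so calibration is
  approximate for clusters much smaller than ~20 genes (the null
  calibration tests run at cluster size 50).
* CAST and template matching operate on 4-point profiles, where Pearson
  correlation is a coarse similarity; distinct behaviour categories can
  correlate up to ~0.8, which is why the cascade (not CAST alone)
  is needed.
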