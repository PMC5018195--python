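# Methods

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention); "overlap" always
means ≥ 1 bp. The promoter window around a TSS is the symmetric
`[TSS − flank, TSS + flank)` with `flank = 2000` bp by default, so gene
strand does not affect classification; gene assignment of non-promoter
peaks uses the span-to-peak gap (0 if overlapping) with a 50-kb default
ceiling, and the promoter rule takes precedence — a peak overlapping a
promoter window is never additionally distance-assigned. A peak
overlapping several TSS windows is counted once. narrowPeak summit
offsets of −1, and BED6 peaks (no summit column), fall back to the
interval midpoint rounded down. Duplicate peak labels get ordinal
suffixes so row labels stay unique.

Two distinct counting rules are used deliberately:

* **Binned density matrices** count *extended fragments*: each tag is
  extended `fragment_length` (default 150 bp, nucleosome scale) in its
  strand direction, and a bin counts fragments overlapping it. This
  reproduces the nucleosomal valley/flank shapes around TF summits that
  5′-end counting flattens.
* **Window RPKM** counts *reads* (tag 5′ positions) inside
  `summit ± half_window` and normalizes per kb of window per million
  library tags, the conventional RPKM reading. Pearson correlations are
  computed on these per-peak RPKMs; since *r* is affine-invariant the
  choice of per-million vs per-10M scaling is immaterial.

Windows running off a chromosome edge are zero-padded (flagged per row)
rather than dropped, so row sets stay aligned across tracks. Depth
equalization downsamples every track in a comparison to the minimum
library size, uniformly without replacement, under a recorded seed.

## Peak callers

The sharp caller scans windows (default 300 bp, step window/2) and tests
the fragment-overlap count against a Poisson null with
λ = library · (window + fragment) / genome length; with a control track,
λ is the maximum of that and the library-scaled local control rate in a
surrounding 10×-window region (without a control only the genome-wide
rate is used, as in classic callers run treatment-only). Significant
windows (raw p below the cutoff, default 1e-5, and fold ≥ 2 over λ) are
merged when they touch; the summit is the leftmost maximum-coverage base
and the score −log10 of the best window p. The broad caller tiles the
genome (default 200 bp), marks tiles with p below the cutoff eligible,
clusters eligible tiles bridging up to `gap` bp (default 600) of
ineligible ones, and keeps clusters whose aggregate count exceeds the
fold threshold over aggregate λ. No multiple-testing correction is
applied inside either caller; thresholds are on raw per-window p-values
and are echoed in all outputs.

Tie-breaks are deterministic throughout: leftmost maximum for summits,
lexicographic label order for equal row totals when sorting heatmap rows.

## Statistics

* Pearson *r* with the two-sided *t* p-value on n − 2 degrees of freedom
  (scipy.stats.pearsonr); an optional label-shuffling permutation p is
  computed alongside, never instead.
* Mann–Whitney U is exact (full null distribution) when
  n₁·n₂ ≤ 10 000 and the pooled deltas are tie-free, otherwise the normal
  approximation with tie and continuity correction. Two-sided by default;
  sidedness is recorded in the result. The delta convention is WT − KD,
  so a knockdown loss appears as a positive delta in the affected group.
* Overlap significance uses a 2×2 table of genome units — non-overlapping
  1-kb tiles by default — scored for overlap with either peak set, and a
  two-sided Fisher's exact test; the unit definition travels inside the
  result object so alternative tilings remain comparable.
* Differential expression is an input, not a computation: tables supply a
  per-gene significance flag (or `padj`, thresholded at 0.05) and a
  log-fold-change whose sign is reported per table for the direct-target
  intersection.

## The synthetic study

The generator emulates the statistical structure of a TF/H3K4-methylation
knockdown experiment on a desk-scale genome. Defaults (all configurable):
one 20-Mb chromosome; 300 non-overlapping genes (2–8 kb); 300 TF sites,
30% within ±1.5 kb of a TSS and the rest ≥ 10 kb from every TSS; 220
additional TF-free distal enhancers; per-site TF occupancy lognormal
(μ=0, σ=0.5). Tag tracks are multinomial draws of exactly the configured
library size (TF 300 k, marks 200 k) from background + per-site signal
components, with background weight 0.015·genome length against per-site
strengths of 30 (TF) and 120 (marks) occupancy units — chosen so the
wild-type TF track is comfortably callable while an 80% occupancy loss
drops most sites below the default detection threshold, mirroring the
disappearance of the TF peak set after knockdown. TF tags scatter as a
Gaussian (σ = 75 bp, absorbing fragment-length variability); mark tags
follow two flanking Gaussians at summit ± 500 bp (σ = 200) with an 80%
central dip carved out by rejection sampling, translated +300 bp at
promoter-context sites (the promoter-shifted H3K4me2/3 pattern) and
symmetric at distal sites. Strands are ± with probability ½ independent
of position; an optional strand-asymmetric TF model shifts + tags
upstream and − tags downstream by `tf_strand_shift` bp and is off by
default.

Mark intensity at a bound site is `(1 − coupling)·base + coupling·occupancy`
with independent lognormal base levels, so the configured coupling
(default 0.6) controls the recoverable occupancy–mark correlation and
r is ~0 at coupling 0. Knockdown multiplies intensities by per-(mark,
context) factors: TF occupancy 0.2 everywhere (an 80% reduction),
H3K4me1 0.5 at bound enhancers, H3K4me3 0.5 at bound promoters, H3K4me2
1.0. Because each track is renormalized to its library size, a planted
loss slightly inflates background and unaffected sites in the knockdown
sample — the same compositional effect real depth-normalized libraries
show. All randomness flows from the single config seed through named
generator streams, so fixtures are bit-identical across runs; fixtures
serialize entirely as plain text (BED6 tags, narrowPeak truth peaks,
TSVs, YAML config, checksummed manifest).

What the generator does *not* model: sequence content and mappability,
PCR duplicates, copy-number variation, fragment-size estimation, and
heavy-tailed occupancy (σ = 0.5 is far tighter than real TF peak
intensity distributions). Passing tests therefore demonstrate that the
pipeline's logic recovers planted structure under idealized sampling
noise, not that it is robust to artifacts of real libraries.

## Validation scenarios and problem sizes

The acceptance suite fixes its scenarios as follows (sizes chosen as
desk-scale study conditions, seeded and frozen):

* **Null calibration:** 1000 replicates of a reduced configuration
  (4-Mb genome, 60 genes, 60 TF sites, 40 TF-free enhancers, 40-k-tag
  H3K4me1 libraries) with every knockdown factor at 1.0; the bound-vs-
  unbound test's rejection rate at α = 0.05 must sit within 3 binomial
  standard errors of 0.05. Group sizes (~42 vs ~40) are large enough for
  the tie-corrected normal approximation the tied RPKM deltas force.
* **Effect recovery:** 100 replicates of the default configuration
  (≥ 200 enhancers per stratum); H3K4me1 (factor 0.5) must reject at
  p < 0.01 in ≥ 95 of them while H3K4me2 (factor 1.0) stays above 0.05 in
  ≥ 90 — the latter bound is the binomial behavior of a well-calibrated
  null test.
* **Correlation recovery:** mean r over 10 seeds at coupling
  0 / 0.3 / 0.6 / 0.9 must be strictly increasing (Spearman ρ = 1).
* **Caller recovery:** the knockdown scenario runs the default
  (strand-symmetric) configuration and requires > 80% wild-type site
  recovery with < 20% on the knockdown track at identical thresholds.
  The summit-precision scenario (≥ 95% of summits within 50 bp) uses the
  strand-asymmetric tag model (shift 75 bp, footprint σ = 35, strength 60
  ≈ 10× local enrichment): with strand-symmetric tags and strand-directed
  extension the expected coverage is exactly flat across ± fragment
  length around the summit, so no caller can localize summits more
  precisely than that plateau — the asymmetric geometry is also what real
  ChIP libraries exhibit and what summit calling is designed for.
* **Metaprofile shapes:** on generated data, distal H3K4me1 metaprofiles
  must show two flanking maxima around a central minimum at the summit,
  and promoter H3K4me3 profiles the same pattern displaced by the
  configured +300-bp shift, each located within ±1–2 bins of 50 bp.

## Known limitations

The callers are deliberately minimal: no fragment-size model building, no
genome-wide FDR, no duplicate-read policies, and the sharp caller's
treatment-only mode uses a single genome-wide λ regime. Promoter windows
are strand-symmetric by design; per-isoform promoter definitions are out
of scope. The Fisher overlap test's tiling unit is a modeling choice —
results depend on it, which is why the unit definition is embedded in
every result. Exact Mann–Whitney enumeration is skipped whenever ties are
present (integer window counts make tied deltas common), falling back to
the tie-corrected asymptotic test even for small groups.
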