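# tfmark

Peak-centric integration of transcription-factor (TF) and histone-mark
ChIP-seq data: quantify H3K4me1/2/3 and polymerase signal around TF peak
summits, classify peaks by genomic context and cell-type sharing, correlate
TF occupancy with mark density, and test for knockdown-induced mark changes
at enhancers and promoters. A built-in synthetic-data generator plants
known ground truth (peak summits, occupancy weights, per-site mark
intensities, knockdown effect sizes), so the entire pipeline can be
exercised and validated without any external data.

The package is written for regulatory-genomics analysts who have aligned
read tags (BED6 or SAM), peak calls (BED6 / narrowPeak) and a TSS/gene
annotation, and want the standard summit-anchored analyses as a tested,
scriptable library rather than a chain of one-off commands.

## What it computes

* **Promoter / non-promoter classification.** A peak is a *promoter* peak
  iff it overlaps `[TSS − 2 kb, TSS + 2 kb)` of any gene by ≥ 1 bp; the
  rest are assigned to every gene within 50 kb (both distances
  configurable). Two peak sets are split into *common* / *specific* by the
  ≥ 1 bp overlap rule, with a Fisher's exact test over 1-kb genome tiles
  for overlap significance.
* **Summit-anchored densities.** For each peak, extended-fragment coverage
  is counted in 50-bp bins over ±5 kb of the summit, giving a peaks × bins
  matrix (heatmap substrate), per-bin mean metaprofiles, and rows sortable
  by a reference (e.g. TF) signal. Libraries are depth-equalized by seeded
  downsampling to the minimum library size.
* **Occupancy–mark correlation.** Per-peak window signals (reads per kb
  per million library tags, RPKM, over summit ± 5 kb) for the TF and a
  mark are compared by Pearson's *r* with a two-sided *t*-distribution
  *p* (a permutation *p* is optional).
* **Knockdown differential.** For a set of centers (e.g. wild-type H3K4me1
  peaks as enhancer proxies), Δ = RPKM(WT) − RPKM(KD) per center; the
  bound stratum (centers overlapping a TF peak by ≥ 1 bp) is compared with
  the unbound stratum by a Mann–Whitney U test (exact enumeration for
  small tie-free groups, tie-corrected normal approximation otherwise).
* **Direct targets.** Genes bound by the TF and significant in every
  supplied differential-expression table, annotated with per-table signs.
* **Minimal peak callers.** A sharp caller (sliding-window Poisson scan
  with optional local lambda, summit at the maximum-coverage base) and a
  broad caller (gap-tolerant clustering of enriched tiles) make the
  synthetic pipeline self-contained end to end.

## Worked example

Run the complete synthetic study — simulate wild-type and TF-knockdown
tracks, call peaks, classify, correlate, and test the knockdown
differentials — with one command:

```sh
tfmark reproduce-synthetic --seed 1 --out run/
cat run/summary.json
```

On the default configuration (20-Mb genome, 300 genes, 300 TF peaks of
which 30% promoter-proximal, 220 TF-free enhancers, 80% TF occupancy loss
and 50% H3K4me1 loss at bound enhancers upon knockdown) this prints,
among others:

```
"n_tf_peaks_wt": 260,          # sharp peaks called on the WT TF track
"n_tf_peaks_kd": 22,           # almost none survive the 80% knockdown
"n_enhancer_domains": 656,     # broad H3K4me1 domains in WT
"correlation_h3k4me1": {"r": 0.331, "p": 4.7e-08, "n": 260},
"diff_h3k4me1": {"U": 72832.0, "p": 1.3e-43, "n_bound": 180, "n_unbound": 476},
"diff_h3k4me2": {"U": 47027.0, "p": 0.053, ...},
"diff_h3k4me3": {"U": 41554.5, "p": 0.553, ...}
```

Reading: TF occupancy correlates positively with mark density across
called TF peaks; upon knockdown the H3K4me1 reduction is far larger at
TF-bound enhancers than at unbound ones (tiny Mann–Whitney *p*), while
the untouched H3K4me2/3 marks show no significant bound-vs-unbound
difference at enhancers — the planted dissociation, recovered from tags
alone. Individual stages are available as `tfmark simulate | callpeaks |
classify | matrix | correlate | diff | targets`, and everything in the
CLI is a thin wrapper over importable functions (`tfmark.classify_promoter`,
`tfmark.build_matrix`, `tfmark.enhancer_differential`, ...).

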