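"""Integration statistics: occupancy-mark correlation, knockdown
differentials, overlap significance, and direct-target intersection.

These are the headline analyses of a TF/histone-mark ChIP-seq integration:

* correlate per-peak TF occupancy with histone-mark density over fixed
  windows around peak summits (Pearson, parametric or permutation p);
* compare wild-type minus knockdown mark RPKM deltas between TF-bound and
  unbound regulatory regions (Mann-Whitney U);
* test the significance of the overlap between two peak sets over a tiled
  genome universe (Fisher's exact test);
* intersect TF-bound genes with differential-expression calls to nominate
  direct targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .density import WindowSignal, window_rpkm
from .intervals import GenomicInterval, Peak, _build_trees
from .peakcall import TagTrack

__all__ = [
    "CorrelationResult",
    "EnhancerDiffResult",
    "OverlapTestResult",
    "occupancy_correlation",
    "enhancer_differential",
    "overlap_significance",
    "make_tiles",
    "direct_targets",
]


@dataclass
class CorrelationResult:
    """Pearson correlation of per-peak TF vs mark window signals."""

    r: float
    p_value: float
    n: int
    p_permutation: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r outside [-1, 1]")
        if self.n < 3:
            raise ValueError("correlation requires n >= 3")


@dataclass
class EnhancerDiffResult:
    """Bound-vs-unbound comparison of WT - KD window RPKM deltas."""

    table: pd.DataFrame  # columns: label, group, delta
    U: float
    p_value: float
    n_bound: int
    n_unbound: int
    alternative: str = "two-sided"
    method: str = "auto"

    def __post_init__(self) -> None:
        if self.n_bound + self.n_unbound != len(self.table):
            raise ValueError("group sizes must sum to the number of centers")
        if not (0 <= self.U <= self.n_bound * self.n_unbound):
            raise ValueError("U outside [0, n_bound * n_unbound]")


@dataclass
class OverlapTestResult:
    """Fisher's exact test on a 2x2 table of genome units by peak overlap."""

    table: np.ndarray  # [[both, a_only], [b_only, neither]]
    odds_ratio: float
    p_value: float
    unit_definition: str = "1 kb genome tiles"

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.shape != (2, 2) or (self.table < 0).any():
            raise ValueError("table must be a nonnegative 2x2 matrix")


def _signal_vectors(
    tf_signal: Sequence[WindowSignal], mark_signal: Sequence[WindowSignal]
) -> tuple[np.ndarray, np.ndarray]:
    tf_map = {s.label: s.rpkm for s in tf_signal}
    mk_map = {s.label: s.rpkm for s in mark_signal}
    if set(tf_map) != set(mk_map) or len(tf_map) != len(tf_signal) or len(mk_map) != len(mark_signal):
        raise ValueError("tf_signal and mark_signal must cover the same peak labels exactly once")
    labels = sorted(tf_map)
    return (
        np.array([tf_map[l] for l in labels], dtype=np.float64),
        np.array([mk_map[l] for l in labels], dtype=np.float64),
    )


def occupancy_correlation(
    tf_signal: Sequence[WindowSignal],
    mark_signal: Sequence[WindowSignal],
    n_permutations: int = 0,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation of TF vs mark per-peak window signals.

    The parametric two-sided p comes from the t distribution with n - 2
    degrees of freedom.  With ``n_permutations > 0`` a permutation p (mark
    vector shuffled) is also reported; the statistic is unchanged.
    Raises on degenerate input: fewer than 3 peaks or zero variance.
    """
    x, y = _signal_vectors(tf_signal, mark_signal)
    n = len(x)
    if n < 3:
        raise ValueError("correlation requires at least 3 peaks")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a signal vector; correlation undefined")
    res = stats.pearsonr(x, y)
    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        perms = rng.permuted(np.tile(yc, (n_permutations, 1)), axis=1)
        r_null = perms @ xc / denom
        p_perm = float((np.sum(np.abs(r_null) >= abs(res.statistic) - 1e-12) + 1)
                       / (n_permutations + 1))
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue),
                             n=n, p_permutation=p_perm)


def mann_whitney(
    bound: np.ndarray,
    unbound: np.ndarray,
    alternative: str = "two-sided",
) -> tuple[float, float, str]:
    """Mann-Whitney U (statistic for the *bound* group) and p-value.

    Exact enumeration when ``n_bound * n_unbound <= 10000`` and the data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    bound = np.asarray(bound, dtype=np.float64)
    unbound = np.asarray(unbound, dtype=np.float64)
    pooled = np.concatenate([bound, unbound])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(bound) * len(unbound) <= 10_000
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(bound, unbound, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue), method


def enhancer_differential(
    wt_track: TagTrack,
    kd_track: TagTrack,
    centers: Sequence[Peak],
    tf_peaks: Sequence[Peak],
    half_window: int = 5000,
    alternative: str = "two-sided",
) -> EnhancerDiffResult:
    """Test whether mark loss upon TF knockdown is larger at TF-bound sites.

    For each center (e.g. a WT H3K4me1 peak) the delta is
    ``window_rpkm(WT) - window_rpkm(KD)`` over ``summit +/- half_window``;
    a center is *bound* iff its own peak interval overlaps any TF peak by
    >= 1 bp.  A planted reduction in the KD sample therefore shows up as a
    positive delta in the bound group.  Bound and unbound deltas are
    compared by a Mann-Whitney U test (two-sided by default).
    """
    if not centers:
        raise ValueError("centers must be nonempty")
    wt = window_rpkm(wt_track, centers, half_window)
    kd = window_rpkm(kd_track, centers, half_window)
    trees = _build_trees(p.interval for p in tf_peaks)
    rows = []
    for c, w, k in zip(centers, wt, kd):
        tree = trees.get(c.interval.chrom)
        bound = tree is not None and tree.overlaps(c.interval.start, c.interval.end)
        rows.append((w.label, "bound" if bound else "unbound", w.rpkm - k.rpkm))
    table = pd.DataFrame(rows, columns=["label", "group", "delta"])
    n_bound = int((table["group"] == "bound").sum())
    n_unbound = len(table) - n_bound
    if n_bound == 0 or n_unbound == 0:
        raise ValueError(
            f"stratification degenerate: {n_bound} bound vs {n_unbound} unbound centers"
        )
    d_bound = table.loc[table["group"] == "bound", "delta"].to_numpy()
    d_unbound = table.loc[table["group"] == "unbound", "delta"].to_numpy()
    U, p, method = mann_whitney(d_bound, d_unbound, alternative=alternative)
    return EnhancerDiffResult(
        table=table, U=U, p_value=p, n_bound=n_bound, n_unbound=n_unbound,
        alternative=alternative, method=method,
    )


def make_tiles(chrom_sizes: Mapping[str, int], tile: int = 1000) -> list[GenomicInterval]:
    """Partition the genome into non-overlapping tiles (last tile clipped)."""
    if tile <= 0:
        raise ValueError("tile must be > 0")
    out = []
    for chrom in sorted(chrom_sizes):
        L = chrom_sizes[chrom]
        for s in range(0, L, tile):
            out.append(GenomicInterval(chrom, s, min(s + tile, L)))
    return out


def overlap_significance(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    universe: Sequence[GenomicInterval],
) -> OverlapTestResult:
    """Fisher's exact test for association between two peak sets.

    Each universe unit (default construction: 1-kb tiles, see
    ``make_tiles``) is scored for >= 1 bp overlap with either peak set,
    giving a 2x2 table [[both, A only], [B only, neither]]; the two-sided
    Fisher exact p and the sample odds ratio are returned.  The unit
    definition travels with the result so alternative constructions stay
    comparable.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    trees_a = _build_trees(p.interval for p in peaks_a)
    trees_b = _build_trees(p.interval for p in peaks_b)

    def hits(trees):
        return np.array([
            (t := trees.get(u.chrom)) is not None and t.overlaps(u.start, u.end)
            for u in universe
        ], dtype=bool)

    in_a, in_b = hits(trees_a), hits(trees_b)
    table = np.array([
        [int(np.sum(in_a & in_b)), int(np.sum(in_a & ~in_b))],
        [int(np.sum(~in_a & in_b)), int(np.sum(~in_a & ~in_b))],
    ])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    sizes = {u.length for u in universe}
    unit_def = f"{min(sizes)}-{max(sizes)} bp genome tiles, n={len(universe)}"
    return OverlapTestResult(table=table, odds_ratio=float(odds), p_value=float(p),
                             unit_definition=unit_def)


def direct_targets(
    bound_genes: set[str],
    de_tables: Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Genes bound by the TF and significant in *every* DE table.

    Each table needs columns ``gene``, ``log2fc`` and ``significant``
    (boolean); DE calling itself is an upstream input.  Returns a frame
    indexed by gene with one sign-of-change column per table
    (``sign_1 .. sign_k``, values +1/-1/0).
    """
    if not de_tables:
        raise ValueError("at least one DE table is required")
    signs: dict[str, list[int]] = {}
    surviving = set(bound_genes)
    per_table_signs = []
    for i, tbl in enumerate(de_tables, start=1):
        for col in ("gene", "log2fc", "significant"):
            if col not in tbl.columns:
                raise ValueError(f"DE table {i} lacks required column {col!r}")
        if tbl["gene"].duplicated().any():
            dups = tbl.loc[tbl["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"DE table {i} has duplicate gene ids: {dups[:5]}")
        sig = tbl.loc[tbl["significant"].astype(bool)]
        surviving &= set(sig["gene"])
        per_table_signs.append(dict(zip(sig["gene"], np.sign(sig["log2fc"]).astype(int))))
    genes = sorted(surviving)
    data = {
        f"sign_{i}": [per_table_signs[i - 1][g] for g in genes]
        for i in range(1, len(de_tables) + 1)
    }
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def read_de_table(path) -> pd.DataFrame:
    """Read a DE table TSV with header.

    Accepts either an explicit boolean ``significant`` column or a ``padj``
    column (significant iff padj < 0.05); the fold-change column may be
    named ``log2fc`` or ``log2FoldChange``.
    """
    tbl = pd.read_csv(path, sep="\t")
    if "log2FoldChange" in tbl.columns and "log2fc" not in tbl.columns:
        tbl = tbl.rename(columns={"log2FoldChange": "log2fc"})
    if "significant" not in tbl.columns:
        if "padj" not in tbl.columns:
            raise ValueError("DE table needs a 'significant' or 'padj' column")
        tbl["significant"] = tbl["padj"] < 0.05
    return tbl[["gene", "log2fc", "significant"]]
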