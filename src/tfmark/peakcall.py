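"""Aligned-tag container and minimal sharp / broad peak callers.

``TagTrack`` stores the 5' positions and strands of aligned ChIP-seq reads
per chromosome as numpy arrays; every counting operation in the package
works on extended fragments (each tag extended ``fragment_length`` bp in its
strand direction, the canonical nucleosome-scale fragment).

Two deliberately small callers are provided so a synthetic pipeline is
self-contained end to end:

* ``call_sharp`` — sliding-window scan against a Poisson background with an
  optional local lambda (MACS-style), summit at the maximum-coverage base;
  suited to point-source factors.
* ``call_broad`` — non-overlapping window tiling with gap-tolerant
  clustering of enriched windows (SICER-style); suited to spread-out
  histone marks.

Neither applies multiple-testing correction: the threshold is on the raw
per-window Poisson p-value, so results are directly interpretable against
the configured cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, Peak

__all__ = ["TagTrack", "CallerConfig", "call_sharp", "call_broad"]

DEFAULT_FRAGMENT_LENGTH = 150


class TagTrack:
    """A sample's aligned-read tags: per-chromosome 5' positions and strands.

    Parameters
    ----------
    sample_id:
        Free-text sample name, carried through to outputs.
    chrom_sizes:
        Mapping chromosome -> length in bp; every tag must lie within.
    positions / strands:
        Per-chromosome int arrays; strands are +1 / -1.
    fragment_length:
        Extension length in bp applied in the tag's strand direction when
        counting coverage.
    """

    def __init__(
        self,
        sample_id: str,
        chrom_sizes: Mapping[str, int],
        positions: Mapping[str, np.ndarray],
        strands: Mapping[str, np.ndarray],
        fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    ) -> None:
        self.sample_id = sample_id
        self.chrom_sizes = dict(chrom_sizes)
        self.positions = {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}
        self.strands = {c: np.asarray(s, dtype=np.int8) for c, s in strands.items()}
        if set(self.positions) != set(self.strands):
            raise ValueError("positions and strands cover different chromosomes")
        for chrom, pos in self.positions.items():
            if chrom not in self.chrom_sizes:
                raise ValueError(f"tags on undeclared chromosome {chrom!r}")
            if len(pos) != len(self.strands[chrom]):
                raise ValueError(f"{chrom}: positions/strands length mismatch")
            if len(pos) and (pos.min() < 0 or pos.max() >= self.chrom_sizes[chrom]):
                raise ValueError(f"{chrom}: tag positions outside [0, {self.chrom_sizes[chrom]})")
        if fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        self.fragment_length = int(fragment_length)

    @property
    def library_size(self) -> int:
        return sum(len(p) for p in self.positions.values())

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def chroms(self) -> list[str]:
        return sorted(self.positions)

    def fragments(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Extended-fragment (start, end) arrays for one chromosome, clipped
        to the chromosome bounds.  Half-open coordinates."""
        pos = self.positions.get(chrom)
        if pos is None or len(pos) == 0:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        strand = self.strands[chrom]
        fl = self.fragment_length
        starts = np.where(strand >= 0, pos, pos - fl + 1)
        ends = starts + fl
        L = self.chrom_sizes[chrom]
        return np.clip(starts, 0, L), np.clip(ends, 0, L)

    def iter_tags(self) -> Iterator[tuple[str, int, str]]:
        """Yield (chrom, 5' position, '+'/'-') per tag, chromosome-sorted."""
        for chrom in self.chroms():
            for pos, strand in zip(self.positions[chrom], self.strands[chrom]):
                yield chrom, int(pos), "+" if strand >= 0 else "-"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TagTrack):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.chrom_sizes == other.chrom_sizes
            and self.fragment_length == other.fragment_length
            and set(self.positions) == set(other.positions)
            and all(
                np.array_equal(self.positions[c], other.positions[c])
                and np.array_equal(self.strands[c], other.strands[c])
                for c in self.positions
            )
        )

    def __repr__(self) -> str:
        return (
            f"TagTrack({self.sample_id!r}, n={self.library_size}, "
            f"chroms={len(self.chrom_sizes)}, fraglen={self.fragment_length})"
        )


@dataclass
class CallerConfig:
    """Peak-caller parameters.

    ``window`` is the scan window (sharp) or tile size (broad) in bp;
    ``gap`` the maximum ineligible span in bp bridged when clustering broad
    windows; ``pvalue_cutoff`` the raw Poisson p threshold; and
    ``min_enrichment`` the minimum fold over the background rate.
    """

    mode: str = "sharp"
    window: int = 300
    gap: int = 600
    pvalue_cutoff: float = 1e-5
    min_enrichment: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("sharp", "broad"):
            raise ValueError(f"mode must be sharp|broad, got {self.mode!r}")
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if not (0 < self.pvalue_cutoff < 1):
            raise ValueError("pvalue_cutoff must be in (0, 1)")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")


def _window_counts(starts: np.ndarray, ends: np.ndarray,
                   win_starts: np.ndarray, win_ends: np.ndarray) -> np.ndarray:
    """Number of fragments overlapping each half-open window by >= 1 bp.

    A fragment [s, e) overlaps [w0, w1) iff s < w1 and e > w0; with e >= s
    this equals |s < w1| - |e <= w0| on sorted arrays.
    """
    s_sorted = np.sort(starts)
    e_sorted = np.sort(ends)
    return (
        np.searchsorted(s_sorted, win_ends, side="left")
        - np.searchsorted(e_sorted, win_starts, side="right")
    )


def _coverage(starts: np.ndarray, ends: np.ndarray, length: int) -> np.ndarray:
    """Per-base fragment coverage via a difference array."""
    diff = np.zeros(length + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    return np.cumsum(diff[:-1])


def _effective_rate(track: TagTrack, window: int) -> float:
    """Expected fragments overlapping a window under a uniform genome-wide
    model: n * (window + fragment_length) / genome_length."""
    return track.library_size * (window + track.fragment_length) / track.genome_length


def call_sharp(
    treatment: TagTrack,
    control: TagTrack | None,
    cfg: CallerConfig,
    genome: Mapping[str, int],
) -> list[Peak]:
    """Call point-source peaks with a sliding-window Poisson scan.

    Windows of ``cfg.window`` bp (step window/2) whose extended-fragment
    count beats lambda at ``cfg.pvalue_cutoff`` and ``cfg.min_enrichment``
    are merged when they touch; the summit is the leftmost maximum-coverage
    base and the score is -log10 of the best window p-value.  Lambda is the
    genome-wide treatment rate; when a control track is given it is the max
    of that and the library-scaled local control rate in a surrounding
    10x-window region.
    """
    if cfg.mode != "sharp":
        raise ValueError("call_sharp requires cfg.mode == 'sharp'")
    if not genome:
        raise ValueError("chromosome sizes are required")
    if treatment.library_size == 0:
        return []

    lam_genome = _effective_rate(treatment, cfg.window)
    scale = (treatment.library_size / control.library_size) if control and control.library_size else 1.0
    step = max(cfg.window // 2, 1)
    peaks: list[Peak] = []

    for chrom in sorted(genome):
        L = genome[chrom]
        starts, ends = treatment.fragments(chrom)
        if len(starts) == 0:
            continue
        win_starts = np.arange(0, max(L - cfg.window, 0) + 1, step, dtype=np.int64)
        win_ends = np.minimum(win_starts + cfg.window, L)
        counts = _window_counts(starts, ends, win_starts, win_ends)

        lam = np.full(len(win_starts), lam_genome, dtype=np.float64)
        if control is not None and control.library_size:
            c_starts, c_ends = control.fragments(chrom)
            region = 10 * cfg.window
            centers = (win_starts + win_ends) // 2
            reg_starts = np.maximum(centers - region // 2, 0)
            reg_ends = np.minimum(centers + region // 2, L)
            local = _window_counts(c_starts, c_ends, reg_starts, reg_ends).astype(np.float64)
            span = np.maximum(reg_ends - reg_starts + control.fragment_length, 1)
            local_rate = scale * local / span * (cfg.window + treatment.fragment_length)
            lam = np.maximum(lam, local_rate)

        pvals = stats.poisson.sf(counts - 1, lam)
        keep = (pvals < cfg.pvalue_cutoff) & (counts >= cfg.min_enrichment * lam)
        if not keep.any():
            continue

        cov = _coverage(starts, ends, L)
        idx = np.flatnonzero(keep)
        # merge windows that touch or overlap into candidate peaks
        merged: list[tuple[int, int, float]] = []
        cur_s, cur_e, cur_p = win_starts[idx[0]], win_ends[idx[0]], pvals[idx[0]]
        for i in idx[1:]:
            if win_starts[i] <= cur_e:
                cur_e = max(cur_e, win_ends[i])
                cur_p = min(cur_p, pvals[i])
            else:
                merged.append((int(cur_s), int(cur_e), float(cur_p)))
                cur_s, cur_e, cur_p = win_starts[i], win_ends[i], pvals[i]
        merged.append((int(cur_s), int(cur_e), float(cur_p)))

        for s, e, p in merged:
            summit = s + int(np.argmax(cov[s:e]))  # argmax is leftmost on ties
            score = float(-np.log10(max(p, 1e-300)))
            peaks.append(
                Peak(GenomicInterval(chrom, s, e), summit=summit, score=score,
                     label=f"{chrom}_sharp_{len(peaks)}")
            )
    return peaks


def call_broad(
    treatment: TagTrack,
    control: TagTrack | None,
    cfg: CallerConfig,
    genome: Mapping[str, int],
) -> list[Peak]:
    """Call broad domains by gap-tolerant clustering of enriched tiles.

    The genome is tiled into non-overlapping ``cfg.window`` windows; a
    window is *eligible* when its Poisson p beats ``cfg.pvalue_cutoff``.
    Consecutive eligible windows are clustered, bridging up to ``cfg.gap``
    bp of ineligible windows; a cluster is kept if its aggregate count
    exceeds ``cfg.min_enrichment`` times its aggregate lambda.  The domain
    score is the sum of -log10 p over eligible windows and the summit is
    the domain midpoint.
    """
    if cfg.mode != "broad":
        raise ValueError("call_broad requires cfg.mode == 'broad'")
    if not genome:
        raise ValueError("chromosome sizes are required")
    if treatment.library_size == 0:
        return []

    lam_genome = _effective_rate(treatment, cfg.window)
    scale = (treatment.library_size / control.library_size) if control and control.library_size else 1.0
    peaks: list[Peak] = []

    for chrom in sorted(genome):
        L = genome[chrom]
        starts, ends = treatment.fragments(chrom)
        if len(starts) == 0:
            continue
        win_starts = np.arange(0, L, cfg.window, dtype=np.int64)
        win_ends = np.minimum(win_starts + cfg.window, L)
        counts = _window_counts(starts, ends, win_starts, win_ends)

        lam = np.full(len(win_starts), lam_genome, dtype=np.float64)
        if control is not None and control.library_size:
            c_starts, c_ends = control.fragments(chrom)
            local = _window_counts(c_starts, c_ends, win_starts, win_ends).astype(np.float64)
            lam = np.maximum(lam, scale * local)

        pvals = stats.poisson.sf(counts - 1, lam)
        eligible = np.flatnonzero(pvals < cfg.pvalue_cutoff)
        if len(eligible) == 0:
            continue

        clusters: list[list[int]] = [[int(eligible[0])]]
        for i in eligible[1:]:
            prev = clusters[-1][-1]
            ineligible_bp = int(win_starts[i] - win_ends[prev])
            if ineligible_bp <= cfg.gap:
                clusters[-1].append(int(i))
            else:
                clusters.append([int(i)])

        for members in clusters:
            first, last = members[0], members[-1]
            dom_s, dom_e = int(win_starts[first]), int(win_ends[last])
            n_wins = last - first + 1
            total = int(counts[first:last + 1].sum())
            total_lam = float(lam[first:last + 1].sum())
            if total < cfg.min_enrichment * total_lam:
                continue
            score = float(np.sum(-np.log10(np.maximum(pvals[members], 1e-300))))
            summit = dom_s + (dom_e - dom_s) // 2
            peaks.append(
                Peak(GenomicInterval(chrom, dom_s, dom_e), summit=summit, score=score,
                     label=f"{chrom}_broad_{len(peaks)}")
            )
    return peaks
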