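"""Synthetic multi-track ChIP-seq generator with planted ground truth.

The generator emulates the statistical structure of a TF / histone-mark
ChIP-seq study well enough to exercise every pipeline stage with known
truth:

* a gene annotation with non-overlapping spans and derived TSSs;
* TF binding sites, a configurable fraction TSS-proximal (within +/- 2 kb
  of a TSS) and the rest distal (>= 10 kb from every TSS), with lognormal
  occupancy weights;
* histone-mark tracks whose per-site tag profiles are two flanking
  Gaussians around the site with a central nucleosome-free dip, translated
  by a fixed shift at promoters (the promoter-shifted H3K4me2/3 pattern)
  and symmetric at distal sites;
* a TF track with a sharp Gaussian footprint at each summit;
* Poisson-like uniform background, exact per-track library sizes, and
  per-condition (wild-type vs knockdown) multiplicative effect sizes:
  TF occupancy loss everywhere, H3K4me1 loss at TF-bound enhancers,
  H3K4me3 loss at TF-bound promoters, H3K4me2 unchanged by default.

Mark intensity at a bound site is a convex mixture
``(1 - coupling) * base + coupling * occupancy`` of an independent
lognormal base level and the site's TF occupancy, so the configured
coupling strength controls the recoverable occupancy-mark correlation.

All randomness flows from ``SimulationConfig.seed`` through per-stream
``numpy`` generators, so identical configs yield bit-identical fixtures.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    AnnotationSet,
    GenomicInterval,
    Peak,
    parse_peaks,
    read_annotation_table,
    write_annotation_table,
    write_peaks,
)
from .peakcall import TagTrack
from .density import read_tags_bed, write_tags_bed

__all__ = [
    "MarkProfile",
    "KnockdownEffects",
    "SimulationConfig",
    "GroundTruth",
    "simulate_ground_truth",
    "simulate_annotation",
    "simulate_tracks",
    "simulate_de_tables",
    "write_fixture",
    "read_fixture",
]


@dataclass
class MarkProfile:
    """Shape and context weighting of one histone-mark track.

    ``flank_offset``/``flank_sd`` place the two nucleosomal flanks at
    ``summit +/- flank_offset`` (sd in bp); ``dip_depth`` in [0, 1] is the
    fractional density depression at the profile center (0 = no valley);
    ``promoter_shift`` translates the whole profile (in the + direction) at
    promoter-context sites; ``promoter_weight``/``distal_weight`` scale the
    mark's expected signal per context (e.g. H3K4me3 is promoter-heavy,
    H3K4me1 enhancer-heavy).
    """

    flank_offset: int = 500
    flank_sd: float = 200.0
    dip_depth: float = 0.8
    promoter_shift: int = 300
    promoter_weight: float = 1.0
    distal_weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dip_depth <= 1.0:
            raise ValueError("dip_depth must be in [0, 1]")
        if self.flank_sd <= 0 or self.flank_offset < 0:
            raise ValueError("flank geometry must be positive")


@dataclass
class KnockdownEffects:
    """Multiplicative intensity factors applied in the knockdown condition.

    Each factor is in (0, 1]; 1.0 means unchanged.  The defaults encode the
    study design: a strong (80%) loss of TF occupancy, mark-specific losses
    restricted to TF-bound sites of the matching context, and an untouched
    control mark.
    """

    tf_occupancy: float = 0.2
    h3k4me1_at_bound_enhancers: float = 0.5
    h3k4me3_at_bound_promoters: float = 0.5
    h3k4me2: float = 1.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 < v <= 1.0:
                raise ValueError(f"kd factor {name} must be in (0, 1], got {v}")


def _default_profiles() -> dict[str, MarkProfile]:
    return {
        "h3k4me1": MarkProfile(promoter_weight=0.3, distal_weight=1.0),
        "h3k4me2": MarkProfile(promoter_weight=1.0, distal_weight=1.0),
        "h3k4me3": MarkProfile(promoter_weight=1.0, distal_weight=0.1),
    }


def _default_libraries() -> dict[str, int]:
    return {"tf": 300_000, "h3k4me1": 200_000, "h3k4me2": 200_000, "h3k4me3": 200_000}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with desk-scale defaults.

    The default genome is a single 20-Mb chromosome carrying 300 genes,
    300 TF peaks (30% promoter-proximal, 70% distal) and 220 TF-free
    enhancers, so both strata of the knockdown comparison hold >= 200
    sites.  ``background_rate`` is expected background weight per bp
    relative to the per-site strength units; the realized track composition
    follows from the weight normalization at the configured library size.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chrS": 20_000_000})
    n_genes: int = 300
    n_tf_peaks: int = 300
    tf_promoter_fraction: float = 0.3
    n_unbound_enhancers: int = 220
    library_sizes: dict[str, int] = field(default_factory=_default_libraries)
    background_rate: float = 0.015
    fragment_length: int = 150
    tf_footprint_sd: float = 75.0
    tf_strand_shift: int = 0
    tf_site_strength: float = 30.0
    mark_site_strength: float = 120.0
    occupancy_mu: float = 0.0
    occupancy_sigma: float = 0.5
    coupling: float = 0.6
    min_site_spacing: int = 10_000
    distal_tss_clearance: int = 10_000
    mark_profiles: dict[str, MarkProfile] = field(default_factory=_default_profiles)
    kd_effects: KnockdownEffects = field(default_factory=KnockdownEffects)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be positive")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if not 0.0 <= self.tf_promoter_fraction <= 1.0:
            raise ValueError("tf_promoter_fraction must be in [0, 1]")
        unknown = set(self.library_sizes) - set(self.mark_profiles) - {"tf"}
        if unknown:
            raise ValueError(f"library_sizes names unknown tracks: {sorted(unknown)}")

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "mark_profiles" in d:
            d["mark_profiles"] = {k: MarkProfile(**v) for k, v in d["mark_profiles"].items()}
        if "kd_effects" in d:
            d["kd_effects"] = KnockdownEffects(**d["kd_effects"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truth: annotation, TF peaks, sites and mark intensities.

    ``sites`` has one row per mark site: label, chrom, summit, context
    (promoter|distal), bound flag, occupancy (NaN when unbound) and gene
    (promoter sites only).  ``intensities`` has one row per (site, mark)
    with the wild-type and knockdown intensity; the knockdown value is the
    wild-type one times the configured effect factor for matching contexts.
    """

    cfg: SimulationConfig
    annotation: AnnotationSet
    tf_peaks: list[Peak]
    sites: pd.DataFrame
    intensities: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return (
            self.cfg == other.cfg
            and self.annotation == other.annotation
            and self.tf_peaks == other.tf_peaks
            and self.sites.equals(other.sites)
            and self.intensities.equals(other.intensities)
        )

    def site_peaks(self, context: str | None = None, width: int = 2000) -> list[Peak]:
        """Mark sites as Peak objects (interval = summit +/- width/2)."""
        sel = self.sites if context is None else self.sites[self.sites["context"] == context]
        out = []
        for row in sel.itertuples():
            L = self.cfg.chrom_sizes[row.chrom]
            lo = max(row.summit - width // 2, 0)
            hi = min(row.summit + width // 2, L)
            out.append(Peak(GenomicInterval(row.chrom, lo, hi), summit=int(row.summit),
                            score=0.0 if np.isnan(row.occupancy) else float(row.occupancy),
                            label=row.site))
        return out

    def enhancer_centers(self, width: int = 2000) -> list[Peak]:
        return self.site_peaks(context="distal", width=width)

    def promoter_centers(self, width: int = 2000) -> list[Peak]:
        return self.site_peaks(context="promoter", width=width)

    def bound_genes(self, max_gene_dist: int = 50_000) -> set[str]:
        """Genes with a promoter TF site or within ``max_gene_dist`` of a
        distal TF summit."""
        out = set(self.sites.loc[(self.sites["context"] == "promoter")
                                 & self.sites["bound"], "gene"])
        for p in self.tf_peaks:
            for gene, span in self.annotation.gene_spans.items():
                d = span.distance(p.interval)
                if d is not None and d <= max_gene_dist:
                    out.add(gene)
        return out


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> AnnotationSet:
    """Place non-overlapping gene spans; raise if the genome is too small."""
    chroms = sorted(cfg.chrom_sizes)
    lengths = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=np.float64)
    per_chrom = rng.multinomial(cfg.n_genes, lengths / lengths.sum())
    tss: dict[str, tuple[str, int, str]] = {}
    spans: dict[str, GenomicInterval] = {}
    gene_i = 0
    min_gap = 2000
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        L = cfg.chrom_sizes[chrom]
        glens = rng.integers(2000, 8001, size=n)
        needed = int(glens.sum()) + (n + 1) * min_gap
        if needed > L:
            raise ValueError(
                f"genome too small: {chrom} needs {needed} bp for {n} genes, has {L}"
            )
        extra = L - needed
        gaps = rng.multinomial(extra, np.full(n + 1, 1.0 / (n + 1))) + min_gap
        pos = 0
        for j in range(n):
            pos += int(gaps[j])
            start, end = pos, pos + int(glens[j])
            pos = end
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            gene = f"g{gene_i:04d}"
            gene_i += 1
            spans[gene] = GenomicInterval(chrom, start, end, strand)
            tss[gene] = (chrom, start if strand == "+" else end - 1, strand)
    return AnnotationSet(tss_records=tss, gene_spans=spans)


def _place_distal(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    ann: AnnotationSet,
    taken: list[tuple[str, int]],
    n: int,
) -> list[tuple[str, int]]:
    """Rejection-sample distal positions >= distal_tss_clearance from every
    TSS and >= min_site_spacing from every already-taken site."""
    chroms = sorted(cfg.chrom_sizes)
    lengths = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=np.float64)
    probs = lengths / lengths.sum()
    tss_by_chrom: dict[str, np.ndarray] = {
        c: np.sort(np.array([t for (cc, t, _s) in ann.tss_records.values() if cc == c]))
        for c in chroms
    }
    occupied: dict[str, list[int]] = {c: [] for c in chroms}
    for c, p in taken:
        occupied[c].append(p)
    out: list[tuple[str, int]] = []
    tries = 0
    max_tries = 2000 * max(n, 1)
    margin = 6000  # keep +/-5 kb windows inside the chromosome
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "genome too small to place requested distal sites with the "
                "configured clearances"
            )
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        L = cfg.chrom_sizes[chrom]
        if L <= 2 * margin:
            continue
        pos = int(rng.integers(margin, L - margin))
        t = tss_by_chrom[chrom]
        if len(t):
            k = np.searchsorted(t, pos)
            near = min(
                abs(pos - t[k - 1]) if k > 0 else np.inf,
                abs(t[k] - pos) if k < len(t) else np.inf,
            )
            if near < cfg.distal_tss_clearance:
                continue
        if any(abs(pos - q) < cfg.min_site_spacing for q in occupied[chrom]):
            continue
        occupied[chrom].append(pos)
        out.append((chrom, pos))
    return out


def simulate_ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Generate annotation, TF peaks, mark sites and per-mark intensities."""
    rng = np.random.default_rng([cfg.seed, 1])
    ann = _place_genes(cfg, rng)
    genes = sorted(ann.tss_records)

    n_prom = int(round(cfg.n_tf_peaks * cfg.tf_promoter_fraction))
    n_dist = cfg.n_tf_peaks - n_prom
    if n_prom > len(genes):
        raise ValueError(f"{n_prom} promoter TF sites requested but only {len(genes)} genes")

    prom_genes = sorted(rng.choice(genes, size=n_prom, replace=False))
    tf_records: list[tuple[str, int, str]] = []  # (chrom, summit, kind)
    taken: list[tuple[str, int]] = []
    for gene in prom_genes:
        chrom, t, _s = ann.tss_records[gene]
        L = cfg.chrom_sizes[chrom]
        summit = int(np.clip(t + rng.integers(-1500, 1501), 200, L - 200))
        tf_records.append((chrom, summit, "promoter"))
        taken.append((chrom, summit))

    distal_bound = _place_distal(cfg, rng, ann, taken, n_dist)
    taken += distal_bound
    distal_unbound = _place_distal(cfg, rng, ann, taken, cfg.n_unbound_enhancers)
    tf_records += [(c, p, "distal") for c, p in distal_bound]

    occ = rng.lognormal(cfg.occupancy_mu, cfg.occupancy_sigma, size=len(tf_records))
    tf_peaks = []
    for i, ((chrom, summit, kind), o) in enumerate(zip(tf_records, occ)):
        L = cfg.chrom_sizes[chrom]
        lo, hi = max(summit - 150, 0), min(summit + 150, L)
        tf_peaks.append(Peak(GenomicInterval(chrom, lo, hi), summit=summit,
                             score=float(o), label=f"tf_{i:04d}"))

    # mark sites: one per gene TSS (promoter context) + all distal positions
    rows = []
    prom_occ = {g: float(occ[i]) for i, g in enumerate(prom_genes)}
    for gene in genes:
        chrom, t, _s = ann.tss_records[gene]
        rows.append({
            "site": f"prom_{gene}", "chrom": chrom, "summit": int(t),
            "context": "promoter", "bound": gene in prom_occ,
            "occupancy": prom_occ.get(gene, np.nan), "gene": gene,
        })
    for j, ((chrom, pos), o) in enumerate(zip(distal_bound, occ[n_prom:])):
        rows.append({
            "site": f"enh_b{j:04d}", "chrom": chrom, "summit": int(pos),
            "context": "distal", "bound": True, "occupancy": float(o), "gene": "",
        })
    for j, (chrom, pos) in enumerate(distal_unbound):
        rows.append({
            "site": f"enh_u{j:04d}", "chrom": chrom, "summit": int(pos),
            "context": "distal", "bound": False, "occupancy": np.nan, "gene": "",
        })
    sites = pd.DataFrame(rows)

    # per-(site, mark) intensities; coupling mixes base level with occupancy
    rng_marks = np.random.default_rng([cfg.seed, 2])
    kd = cfg.kd_effects
    irows = []
    for mark in sorted(cfg.mark_profiles):
        base = rng_marks.lognormal(cfg.occupancy_mu, cfg.occupancy_sigma, size=len(sites))
        for (row, b) in zip(sites.itertuples(), base):
            if row.bound:
                wt = (1.0 - cfg.coupling) * b + cfg.coupling * row.occupancy
            else:
                wt = b
            factor = 1.0
            if mark == "h3k4me1" and row.bound and row.context == "distal":
                factor = kd.h3k4me1_at_bound_enhancers
            elif mark == "h3k4me3" and row.bound and row.context == "promoter":
                factor = kd.h3k4me3_at_bound_promoters
            elif mark == "h3k4me2":
                factor = kd.h3k4me2
            irows.append({"site": row.site, "mark": mark,
                          "wt": float(wt), "kd": float(wt * factor)})
    intensities = pd.DataFrame(irows)
    return GroundTruth(cfg=cfg, annotation=ann, tf_peaks=tf_peaks,
                       sites=sites, intensities=intensities)


def simulate_annotation(cfg: SimulationConfig) -> tuple[AnnotationSet, list[Peak]]:
    """Annotation and planted TF peaks only (see ``simulate_ground_truth``)."""
    truth = simulate_ground_truth(cfg)
    return truth.annotation, truth.tf_peaks


# ---------------------------------------------------------------------------
# Track generation
# ---------------------------------------------------------------------------

def _draw_mark_offsets(
    rng: np.random.Generator, profile: MarkProfile, n: int
) -> np.ndarray:
    """Offsets from the profile center: two flanking Gaussians with a
    central dip carved out by rejection."""
    if n == 0:
        return np.empty(0, dtype=np.float64)
    dip_sd = profile.flank_offset / 2.0 if profile.flank_offset > 0 else profile.flank_sd / 2.0
    out = np.empty(n, dtype=np.float64)
    pending = np.arange(n)
    while len(pending):
        m = len(pending)
        side = rng.integers(0, 2, size=m) * 2 - 1
        x = rng.normal(0.0, profile.flank_sd, size=m) + side * profile.flank_offset
        u = rng.random(m)
        reject = u < profile.dip_depth * np.exp(-(x**2) / (2.0 * dip_sd**2))
        out[pending[~reject]] = x[~reject]
        pending = pending[reject]
    return out


def _track_components(
    cfg: SimulationConfig, truth: GroundTruth, name: str, condition: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (chrom index, summit, shift, weight) arrays for one track."""
    chroms = sorted(cfg.chrom_sizes)
    cindex = {c: i for i, c in enumerate(chroms)}
    if name == "tf":
        factor = cfg.kd_effects.tf_occupancy if condition == "kd" else 1.0
        ci = np.array([cindex[p.interval.chrom] for p in truth.tf_peaks])
        summits = np.array([p.summit for p in truth.tf_peaks], dtype=np.int64)
        weights = np.array([p.score for p in truth.tf_peaks]) * cfg.tf_site_strength * factor
        shifts = np.zeros(len(summits), dtype=np.int64)
        return ci, summits, shifts, weights
    profile = cfg.mark_profiles[name]
    inten = truth.intensities[truth.intensities["mark"] == name].set_index("site")
    col = "kd" if condition == "kd" else "wt"
    ci, summits, shifts, weights = [], [], [], []
    for row in truth.sites.itertuples():
        w_ctx = profile.promoter_weight if row.context == "promoter" else profile.distal_weight
        ci.append(cindex[row.chrom])
        summits.append(row.summit)
        shifts.append(profile.promoter_shift if row.context == "promoter" else 0)
        weights.append(cfg.mark_site_strength * w_ctx * float(inten.loc[row.site, col]))
    return (np.array(ci), np.array(summits, dtype=np.int64),
            np.array(shifts, dtype=np.int64), np.array(weights, dtype=np.float64))


def simulate_tracks(
    cfg: SimulationConfig,
    truth: GroundTruth,
    condition: str,
    tracks: Sequence[str] | None = None,
) -> dict[str, TagTrack]:
    """Draw tag tracks for one condition; each track has exactly its
    configured library size.

    Tag positions come from a mixture of uniform background (weight
    ``background_rate * genome_length``) and per-site signal components
    (weight proportional to site intensity, knockdown-adjusted).  Strands
    are +/- with probability 1/2 independent of position; an optional
    strand-asymmetric TF model (``tf_strand_shift``) shifts + tags upstream
    and - tags downstream of the summit.
    """
    if condition not in ("wt", "kd"):
        raise ValueError(f"condition must be wt|kd, got {condition!r}")
    names = sorted(cfg.library_sizes) if tracks is None else list(tracks)
    for name in names:
        if name != "tf" and name not in cfg.mark_profiles:
            raise ValueError(f"unknown track name {name!r}")
    chroms = sorted(cfg.chrom_sizes)
    chrom_len = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=np.int64)
    out: dict[str, TagTrack] = {}
    cond_i = 0 if condition == "wt" else 1
    all_names = sorted(cfg.library_sizes)
    for name in names:
        ti = all_names.index(name) if name in all_names else len(all_names)
        rng = np.random.default_rng([cfg.seed, 100 + ti, cond_i])
        lib = cfg.library_sizes.get(name)
        if lib is None:
            raise ValueError(f"no library size configured for track {name!r}")
        ci, summits, shifts, site_w = _track_components(cfg, truth, name, condition)
        bg_w = cfg.background_rate * cfg.genome_length
        weights = np.concatenate([[bg_w], site_w])
        counts = rng.multinomial(lib, weights / weights.sum())

        tag_chrom = np.empty(lib, dtype=np.int64)
        tag_pos = np.empty(lib, dtype=np.int64)
        # background: uniform over the genome
        n_bg = counts[0]
        bg_chrom = rng.choice(len(chroms), size=n_bg, p=chrom_len / chrom_len.sum()) \
            if len(chroms) > 1 else np.zeros(n_bg, dtype=np.int64)
        bg_pos = rng.integers(0, chrom_len[bg_chrom]) if n_bg else np.empty(0, dtype=np.int64)
        tag_chrom[:n_bg] = bg_chrom
        tag_pos[:n_bg] = bg_pos
        # signal: per-site draws
        n_sig = lib - n_bg
        site_idx = np.repeat(np.arange(len(site_w)), counts[1:])
        strand = rng.integers(0, 2, size=lib).astype(np.int8) * 2 - 1
        if n_sig:
            if name == "tf":
                offs = rng.normal(0.0, cfg.tf_footprint_sd, size=n_sig)
                if cfg.tf_strand_shift:
                    offs = offs - strand[n_bg:] * cfg.tf_strand_shift
            else:
                offs = _draw_mark_offsets(rng, cfg.mark_profiles[name], n_sig)
            pos = summits[site_idx] + shifts[site_idx] + np.rint(offs).astype(np.int64)
            lens = chrom_len[ci[site_idx]]
            tag_pos[n_bg:] = np.clip(pos, 0, lens - 1)
            tag_chrom[n_bg:] = ci[site_idx]

        positions = {c: tag_pos[tag_chrom == i] for i, c in enumerate(chroms)}
        strands = {c: strand[tag_chrom == i] for i, c in enumerate(chroms)}
        out[name] = TagTrack(
            sample_id=f"{name}_{condition}",
            chrom_sizes=cfg.chrom_sizes,
            positions=positions,
            strands=strands,
            fragment_length=cfg.fragment_length,
        )
    return out


def simulate_de_tables(
    truth: GroundTruth,
    seed: int,
    n_tables: int = 2,
    p_bound_de: float = 0.35,
    p_background_de: float = 0.02,
) -> list[pd.DataFrame]:
    """Synthetic differential-expression calls per knockdown line.

    TF-bound genes are called significant with probability ``p_bound_de``
    (mostly down-regulated, log2fc ~ N(-1, 0.5)); any gene may be a
    background call with probability ``p_background_de`` (log2fc ~ N(0, 1)).
    Returns one table per line with columns gene / log2fc / significant.
    """
    bound = truth.bound_genes()
    genes = sorted(truth.annotation.tss_records)
    rng = np.random.default_rng([truth.cfg.seed, 3, seed])
    tables = []
    for _ in range(n_tables):
        sig = np.zeros(len(genes), dtype=bool)
        lfc = rng.normal(0.0, 0.2, size=len(genes))
        for i, g in enumerate(genes):
            if g in bound and rng.random() < p_bound_de:
                sig[i] = True
                lfc[i] = rng.normal(-1.0, 0.5)
            elif rng.random() < p_background_de:
                sig[i] = True
                lfc[i] = rng.normal(0.0, 1.0)
        tables.append(pd.DataFrame({"gene": genes, "log2fc": lfc, "significant": sig}))
    return tables


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(
    truth: GroundTruth,
    tracks: Mapping[str, TagTrack],
    out_dir: str | Path,
) -> dict:
    """Write a complete plain-text fixture and return its manifest.

    Layout: ``config.yaml``, ``annotation.tsv``, ``truth_peaks.narrowPeak``,
    ``sites.tsv``, ``intensities.tsv``, ``tags/<name>.bed`` per track (name
    conventionally ``<track>_<condition>``), and ``manifest.json`` with
    sha256 checksums of every file.  ``read_fixture`` reproduces identical
    in-memory objects.
    """
    out = Path(out_dir)
    (out / "tags").mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(truth.cfg.to_dict(), fh, sort_keys=True)
    write_annotation_table(truth.annotation, out / "annotation.tsv")
    write_peaks(truth.tf_peaks, out / "truth_peaks.narrowPeak", dialect="narrowPeak")
    truth.sites.to_csv(out / "sites.tsv", sep="\t", index=False, float_format="%.17g")
    truth.intensities.to_csv(out / "intensities.tsv", sep="\t", index=False,
                             float_format="%.17g")
    for name in sorted(tracks):
        write_tags_bed(tracks[name], out / "tags" / f"{name}.bed")
    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "n_tracks": len(tracks),
        "files": {f: _sha256(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_fixture(fixture_dir: str | Path) -> tuple[GroundTruth, dict[str, TagTrack]]:
    """Reload a fixture written by ``write_fixture``."""
    d = Path(fixture_dir)
    with open(d / "config.yaml") as fh:
        cfg = SimulationConfig.from_dict(yaml.safe_load(fh))
    ann = read_annotation_table(d / "annotation.tsv")
    tf_peaks = parse_peaks(d / "truth_peaks.narrowPeak", dialect="narrowPeak")
    # writers sort by coordinate; restore generation order by label
    tf_peaks = sorted(tf_peaks, key=lambda p: p.label)
    sites = pd.read_csv(d / "sites.tsv", sep="\t", dtype={"gene": str},
                        float_precision="round_trip")
    sites["gene"] = sites["gene"].fillna("")
    if sites["bound"].dtype != bool:
        sites["bound"] = sites["bound"].map({"True": True, "False": False}).astype(bool)
    intensities = pd.read_csv(d / "intensities.tsv", sep="\t",
                              float_precision="round_trip")
    truth = GroundTruth(cfg=cfg, annotation=ann, tf_peaks=tf_peaks,
                        sites=sites, intensities=intensities)
    tracks: dict[str, TagTrack] = {}
    tags_dir = d / "tags"
    if tags_dir.is_dir():
        for bed in sorted(tags_dir.glob("*.bed")):
            name = bed.stem
            tracks[name] = read_tags_bed(bed, name, cfg.chrom_sizes,
                                         fragment_length=cfg.fragment_length)
    return truth, tracks
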