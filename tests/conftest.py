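"""Shared fixtures: tiny deterministic tracks, peaks and configs."""

import numpy as np
import pytest

from tfmark import (
    GenomicInterval,
    MarkProfile,
    KnockdownEffects,
    Peak,
    SimulationConfig,
    TagTrack,
)

CHROM = "chrT"
CHROM_LEN = 1_000_000


def make_track(positions, strands=None, chrom=CHROM, chrom_len=CHROM_LEN,
               fragment_length=150, sample_id="t"):
    """TagTrack on a single chromosome from plain position lists."""
    positions = np.asarray(positions, dtype=np.int64)
    if strands is None:
        strands = np.ones(len(positions), dtype=np.int8)
    return TagTrack(
        sample_id=sample_id,
        chrom_sizes={chrom: chrom_len},
        positions={chrom: positions},
        strands={chrom: np.asarray(strands, dtype=np.int8)},
        fragment_length=fragment_length,
    )


def random_track(rng, n, chrom=CHROM, chrom_len=CHROM_LEN, fragment_length=150):
    return make_track(
        rng.integers(0, chrom_len, size=n),
        strands=rng.integers(0, 2, size=n) * 2 - 1,
        chrom=chrom, chrom_len=chrom_len, fragment_length=fragment_length,
    )


def make_peak(start, end, summit=None, chrom=CHROM, label="p", score=1.0):
    if summit is None:
        summit = start + (end - start) // 2
    return Peak(GenomicInterval(chrom, start, end), summit=summit, score=score, label=label)


def random_peaks(rng, n, chrom=CHROM, chrom_len=CHROM_LEN, min_len=100, max_len=2000):
    out = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - max_len))
        length = int(rng.integers(min_len, max_len))
        summit = start + int(rng.integers(0, length))
        out.append(Peak(GenomicInterval(chrom, start, start + length),
                        summit=summit, score=float(rng.random()), label=f"p{i:05d}"))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale simulation config for fast whole-pipeline tests."""
    return SimulationConfig(
        seed=5,
        chrom_sizes={"chrS": 4_000_000},
        n_genes=60,
        n_tf_peaks=60,
        n_unbound_enhancers=40,
        library_sizes={"tf": 60_000, "h3k4me1": 40_000,
                       "h3k4me2": 40_000, "h3k4me3": 40_000},
    )


def null_sim_config(seed):
    """No knockdown effect anywhere; H3K4me1 only, small genome."""
    return SimulationConfig(
        seed=seed,
        chrom_sizes={"chrS": 4_000_000},
        n_genes=60,
        n_tf_peaks=60,
        n_unbound_enhancers=40,
        library_sizes={"h3k4me1": 40_000},
        mark_profiles={"h3k4me1": MarkProfile(promoter_weight=0.3, distal_weight=1.0)},
        kd_effects=KnockdownEffects(
            tf_occupancy=1.0,
            h3k4me1_at_bound_enhancers=1.0,
            h3k4me3_at_bound_promoters=1.0,
            h3k4me2=1.0,
        ),
    )
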