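"""Correlation, rank-test, overlap-test and target-intersection statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfmark import (
    GenomicInterval,
    WindowSignal,
    direct_targets,
    enhancer_differential,
    make_tiles,
    occupancy_correlation,
    overlap_significance,
)
from tfmark.integrate import mann_whitney

from conftest import CHROM, CHROM_LEN, make_peak, make_track


def _signals(values, prefix="p"):
    return [
        WindowSignal(label=f"{prefix}{i:03d}",
                     window=GenomicInterval(CHROM, i * 20_000, i * 20_000 + 10_000),
                     tag_count=int(abs(v) * 10) + 1, rpkm=float(v))
        for i, v in enumerate(values)
    ]


class TestOccupancyCorrelation:
    def test_identical_vectors_give_r_one(self, rng):
        v = rng.random(30) + 0.1
        res = occupancy_correlation(_signals(v), _signals(v))
        assert res.r == pytest.approx(1.0)

    def test_reflected_vector_gives_r_minus_one(self, rng):
        v = rng.random(30) + 0.1
        res = occupancy_correlation(_signals(v), _signals(v.max() + v.min() - v))
        assert res.r == pytest.approx(-1.0)

    def test_matches_closed_form_and_permutation_oracle(self, rng):
        n = 20
        x = rng.normal(0, 1, n)
        y = 0.4 * x + rng.normal(0, 1, n)
        res = occupancy_correlation(_signals(np.abs(x) + 1), _signals(np.abs(y) + 1),
                                    n_permutations=100_000, seed=3)
        xs, ys = np.abs(x) + 1, np.abs(y) + 1
        # closed-form oracle: r from covariance, p from t with n-2 df
        r_oracle = np.corrcoef(np.sort(xs), ys[np.argsort(xs)])[0, 1]  # label-sorted
        # labels sort identically to index order here, so plain corrcoef applies
        r_plain = np.corrcoef(xs, ys)[0, 1]
        t = r_plain * np.sqrt((n - 2) / (1 - r_plain**2))
        p_oracle = 2 * stats.t.sf(abs(t), n - 2)
        assert res.r == pytest.approx(r_plain, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)
        # independent permutation oracle
        rng2 = np.random.default_rng(99)
        null = np.array([
            abs(np.corrcoef(xs, rng2.permutation(ys))[0, 1]) for _ in range(5000)
        ])
        p_perm_oracle = (np.sum(null >= abs(r_plain)) + 1) / 5001
        se = np.sqrt(p_perm_oracle * (1 - p_perm_oracle) / 5000)
        assert res.p_permutation == pytest.approx(p_perm_oracle, abs=4 * se + 1e-3)

    def test_invariant_under_affine_rescaling(self, rng):
        x = rng.random(25) + 0.5
        y = rng.random(25) + 0.5
        base = occupancy_correlation(_signals(x), _signals(y))
        scaled = occupancy_correlation(_signals(3.5 * x + 2), _signals(y))
        assert scaled.r == pytest.approx(base.r, abs=1e-12)

    def test_degenerate_inputs_error(self, rng):
        flat = _signals(np.ones(10))
        var = _signals(rng.random(10) + 0.1)
        with pytest.raises(ValueError, match="variance"):
            occupancy_correlation(flat, var)
        with pytest.raises(ValueError, match="label"):
            occupancy_correlation(_signals(np.arange(5) + 1.0, prefix="a"),
                                  _signals(np.arange(5) + 1.0, prefix="b"))


def mann_whitney_enumeration_oracle(a, b):
    """Exact two-sided p by exhaustive enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    mid = len(a) * len(b) / 2
    us = np.array([u_of(c) for c in itertools.combinations(range(len(pooled)), n1)])
    # two-sided: as extreme in either direction around the mean
    return float(np.mean(np.abs(us - mid) >= abs(u_obs - mid) - 1e-9))


class TestMannWhitney:
    def test_frozen_example_all_bound_exceed_unbound(self):
        # U = 9 (every bound delta beats every unbound delta);
        # exact two-sided p = 2 * (1 / C(6,3)) = 0.1
        U, p, method = mann_whitney(np.array([3., 4., 5.]), np.array([0., 1., 2.]))
        assert U == 9.0
        assert p == pytest.approx(0.1)
        assert method == "exact"

    @pytest.mark.parametrize("n1,n2", [(4, 5), (6, 6), (8, 8)])
    def test_exact_p_matches_enumeration(self, rng, n1, n2):
        a = rng.normal(1, 1, n1)
        b = rng.normal(0, 1, n2)
        U, p, method = mann_whitney(a, b)
        assert method == "exact"
        assert p == pytest.approx(mann_whitney_enumeration_oracle(a, b), abs=1e-10)


def _site_track(summits, tags_per_site, rng, extra_bg=2000):
    pos = list(rng.integers(0, CHROM_LEN, size=extra_bg))
    for s, n in zip(summits, tags_per_site):
        pos += list(np.clip(np.rint(rng.normal(s, 400, size=n)), 0, CHROM_LEN - 1).astype(int))
    return make_track(pos, rng.integers(0, 2, size=len(pos)) * 2 - 1)


class TestEnhancerDifferential:
    def _centers_and_tf(self):
        centers = [make_peak(i * 30_000 + 10_000, i * 30_000 + 12_000, label=f"c{i:02d}")
                   for i in range(20)]
        tf = [make_peak(i * 30_000 + 10_500, i * 30_000 + 11_000, label=f"tf{i}")
              for i in range(10)]  # first 10 centers are bound
        return centers, tf

    def test_identical_tracks_give_zero_deltas_and_p_one(self, rng):
        centers, tf = self._centers_and_tf()
        track = _site_track([c.summit for c in centers], [40] * 20, rng)
        res = enhancer_differential(track, track, centers, tf)
        assert np.allclose(res.table["delta"], 0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.n_bound == 10 and res.n_unbound == 10

    def test_planted_reduction_gives_positive_bound_delta(self, rng):
        centers, tf = self._centers_and_tf()
        wt_tags = [60] * 20
        kd_tags = [20] * 10 + [60] * 10  # bound sites lose signal in KD
        wt = _site_track([c.summit for c in centers], wt_tags, rng)
        kd = _site_track([c.summit for c in centers], kd_tags, rng)
        res = enhancer_differential(wt, kd, centers, tf)
        bound = res.table[res.table["group"] == "bound"]["delta"]
        unbound = res.table[res.table["group"] == "unbound"]["delta"]
        assert bound.median() > unbound.median()
        assert res.p_value < 0.01

    def test_empty_stratum_reports_counts(self, rng):
        centers, _ = self._centers_and_tf()
        track = _site_track([c.summit for c in centers], [10] * 20, rng)
        with pytest.raises(ValueError, match="0 bound"):
            enhancer_differential(track, track, centers, tf_peaks=[])


class TestOverlapSignificance:
    def test_identical_unit_sets_are_maximally_associated(self):
        universe = make_tiles({CHROM: 1_000_000}, tile=1000)
        peaks = [make_peak(i * 10_000, i * 10_000 + 500) for i in range(50)]
        res = overlap_significance(peaks, list(peaks), universe)
        assert np.isinf(res.odds_ratio)
        # minimal possible p for these margins: choose 50 of 1000 units twice
        p_min = stats.hypergeom(1000, 50, 50).pmf(50)
        assert res.p_value == pytest.approx(p_min, rel=1e-8)

    def test_independence_table_gives_or_one_p_one(self):
        # constructed peaks marking units so the 2x2 table is (10,10,10,10)
        universe = make_tiles({CHROM: 40_000}, tile=1000)
        a = [make_peak(i * 1000, i * 1000 + 10) for i in range(20)]
        b = [make_peak(i * 1000, i * 1000 + 10) for i in range(10)] + \
            [make_peak(i * 1000, i * 1000 + 10) for i in range(20, 30)]
        res = overlap_significance(a, b, universe)
        assert res.table.tolist() == [[10, 10], [10, 10]]
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_p_matches_hypergeometric_tail_oracle(self, rng):
        for _ in range(20):
            universe = make_tiles({CHROM: 30_000}, tile=1000)  # 30 units
            a_units = rng.choice(30, size=rng.integers(3, 15), replace=False)
            b_units = rng.choice(30, size=rng.integers(3, 15), replace=False)
            a = [make_peak(int(u) * 1000, int(u) * 1000 + 10) for u in a_units]
            b = [make_peak(int(u) * 1000, int(u) * 1000 + 10) for u in b_units]
            res = overlap_significance(a, b, universe)
            # oracle: sum hypergeometric pmf of all tables as or less probable
            M, nA, nB = 30, len(a_units), len(b_units)
            k_obs = len(set(a_units) & set(b_units))
            dist = stats.hypergeom(M, nA, nB)
            probs = dist.pmf(np.arange(0, min(nA, nB) + 1))
            p_oracle = probs[probs <= dist.pmf(k_obs) * (1 + 1e-10)].sum()
            assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_symmetric_in_a_and_b(self, rng):
        universe = make_tiles({CHROM: 100_000}, tile=1000)
        a = [make_peak(int(u) * 1000, int(u) * 1000 + 800)
             for u in rng.choice(100, 20, replace=False)]
        b = [make_peak(int(u) * 1000, int(u) * 1000 + 800)
             for u in rng.choice(100, 30, replace=False)]
        assert overlap_significance(a, b, universe).p_value == pytest.approx(
            overlap_significance(b, a, universe).p_value, rel=1e-12)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            overlap_significance([], [], [])


def _de(genes_sig, all_genes, lfc=None):
    lfc = lfc or {}
    return pd.DataFrame({
        "gene": all_genes,
        "log2fc": [lfc.get(g, -1.0 if g in genes_sig else 0.0) for g in all_genes],
        "significant": [g in genes_sig for g in all_genes],
    })


class TestDirectTargets:
    ALL = [f"g{i}" for i in range(10)]

    def test_empty_bound_set_gives_empty_result(self):
        res = direct_targets(set(), [_de({"g1"}, self.ALL)])
        assert len(res) == 0

    def test_intersection_over_tables(self):
        res = direct_targets({"g1", "g2", "g3"},
                             [_de({"g1", "g2"}, self.ALL), _de({"g2", "g3"}, self.ALL)])
        assert list(res.index) == ["g2"]
        assert res.loc["g2", "sign_1"] == -1

    def test_matches_brute_force_intersection(self, rng):
        for _ in range(20):
            bound = {f"g{i}" for i in rng.choice(10, rng.integers(1, 8), replace=False)}
            sigs = [
                {f"g{i}" for i in rng.choice(10, rng.integers(1, 8), replace=False)}
                for _ in range(3)
            ]
            res = direct_targets(bound, [_de(s, self.ALL) for s in sigs])
            oracle = bound & sigs[0] & sigs[1] & sigs[2]
            assert set(res.index) == oracle

    def test_duplicate_gene_ids_error(self):
        tbl = _de({"g1"}, ["g1", "g1", "g2"])
        with pytest.raises(ValueError, match="duplicate"):
            direct_targets({"g1"}, [tbl])
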