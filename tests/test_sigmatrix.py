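"""Pairwise significance matrices, status vectors, binning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methgrad import sigmatrix
from methgrad.sigmatrix import (
    REGIONS,
    SignificanceMatrix,
    bin_sites,
    cosine_similarity,
    fisher_jenks_breaks,
    fisher_jenks_cost,
    neighbor_significant_proportion,
    pairwise_region_tests,
    status_vector,
)


def test_consistent_shift_gives_exact_minimal_p():
    """12 patients all lower in TC than P5 -> one-tailed exact P = 1/4096."""
    rng = np.random.default_rng(0)
    values = np.full((12, 7), np.nan)
    values[:, 0] = rng.uniform(0.2, 0.3, 12)
    values[:, 2] = values[:, 0] + rng.uniform(0.1, 0.2, 12)
    m = pairwise_region_tests(values)
    assert m.sig[0, 2] and m.sig[2, 0]
    assert m.dir[0, 2] == -1 and m.dir[2, 0] == +1
    assert m.p_low[0, 2] == pytest.approx(1 / 4096)


def test_identical_regions_not_significant():
    values = np.full((12, 7), np.nan)
    values[:, 0] = np.linspace(0.1, 0.9, 12)
    values[:, 1] = values[:, 0]  # TC == TE per patient: zero differences dropped
    m = pairwise_region_tests(values)
    assert not m.sig[0, 1]
    assert m.dir[0, 1] == 0


def test_untestable_pair_under_missingness_marked_not_significant():
    values = np.full((12, 7), np.nan)
    values[:, 0] = 0.2
    values[:5, 3] = 0.8  # only 5 complete pairs < min_pairs=6
    m = pairwise_region_tests(values, min_pairs=6)
    assert not m.sig[0, 3]


def test_matrix_matches_independent_test_reimplementation(rng):
    """n_significant_pairs equals a from-scratch two-sided wilcoxon recount."""
    for _ in range(10):
        values = rng.uniform(0, 1, size=(12, 7))
        values[rng.random(values.shape) < 0.1] = np.nan
        m = pairwise_region_tests(values)
        count = 0
        for i in range(7):
            for j in range(i + 1, 7):
                ok = np.isfinite(values[:, i]) & np.isfinite(values[:, j])
                if ok.sum() < 6:
                    continue
                d = values[ok, i] - values[ok, j]
                d = d[d != 0]
                if d.size == 0:
                    continue
                # two one-sided tests at alpha each == one two-sided at 2*alpha
                p2 = stats.wilcoxon(d, zero_method="wilcox", method="auto").pvalue
                if p2 / 2 < 0.05:
                    count += 1
        assert m.n_significant_pairs == count


def test_matrix_invariant_under_patient_permutation(rng):
    values = rng.uniform(0, 1, size=(12, 7))
    m1 = pairwise_region_tests(values)
    m2 = pairwise_region_tests(values[rng.permutation(12)])
    assert np.array_equal(m1.sig, m2.sig)
    assert np.array_equal(m1.dir, m2.dir)


def test_too_few_patients_rejected():
    with pytest.raises(ValueError, match="3 patients"):
        pairwise_region_tests(np.full((2, 7), 0.5))


class TestStatusVector:
    def test_all_false_matrix_gives_zero_vector(self):
        m = SignificanceMatrix.from_pairs([])
        assert status_vector(m).sum() == 0

    def test_one_pair_gives_two_ones(self):
        m = SignificanceMatrix.from_pairs([("TC", "PN")])
        v = status_vector(m)
        assert v.sum() == 2
        assert len(v) == 42

    def test_ones_count_is_twice_pair_count(self, rng):
        pairs = [("TC", "P5"), ("TE", "PN"), ("P10", "P20")]
        m = SignificanceMatrix.from_pairs(pairs)
        assert status_vector(m).sum() == 2 * m.n_significant_pairs


class TestCosine:
    def test_identity_and_orthogonality(self):
        a = np.array([1.0, 0, 1, 0])
        b = np.array([0.0, 1, 0, 1])
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(a, b) == pytest.approx(0.0)

    def test_partial_overlap(self):
        a = np.array([1, 1, 1, 1, 0, 0], dtype=float)
        b = np.array([1, 1, 0, 0, 0, 0], dtype=float)
        assert cosine_similarity(a, b) == pytest.approx(2 / np.sqrt(8))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(4), np.ones(4))


class TestNeighborProportion:
    def test_lone_site_has_no_neighbor(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        assert neighbor_significant_proportion(sites).iloc[0] == 0.0

    def test_window_boundary_inclusive_at_30_exclusive_at_31(self):
        exactly = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 130]})
        beyond = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 131]})
        assert neighbor_significant_proportion(exactly).iloc[0] == 1.0
        assert neighbor_significant_proportion(beyond).iloc[0] == 0.0

    def test_neighbors_do_not_cross_chromosomes(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [100, 110]})
        assert neighbor_significant_proportion(sites).iloc[0] == 0.0

    def test_matches_brute_force_pair_scan(self, rng):
        sites = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 200),
                "pos": rng.integers(1, 2000, 200),
            }
        )
        got = sigmatrix.has_neighbor_within(sites, sites, 30)
        for i in range(len(sites)):
            expect = any(
                j != i
                and sites.chrom[j] == sites.chrom[i]
                and abs(int(sites.pos[j]) - int(sites.pos[i])) <= 30
                for j in range(len(sites))
            )
            assert got[i] == expect


class TestBinning:
    def test_paper_scheme_open_bins(self):
        ba = bin_sites(np.array([-0.03, -0.025, 0.0, 0.19, 0.2, 0.25]))
        assert ba.n_bins == 11
        assert ba.ids[0] == 0  # -0.03 -> start bin
        assert ba.ids[1] == 0  # boundary <= -0.025 belongs to the start bin
        assert ba.ids[-2] == 9  # 0.2 ends the last interior bin
        assert ba.ids[-1] == 10  # > 0.2 -> end bin

    def test_quantile_bins_equal_sized(self, rng):
        v = rng.normal(size=1000)
        ba = bin_sites(v, "quantile", k=10)
        counts = np.bincount(ba.ids)
        assert counts.min() == counts.max() == 100

    def test_gmm_em_separates_two_modes(self, rng):
        v = np.concatenate([rng.normal(0, 0.5, 300), rng.normal(10, 0.5, 300)])
        ba = bin_sites(v, "gmm_em", k=2)
        assert set(ba.ids[:300]) == {0} and set(ba.ids[300:]) == {1}

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            bin_sites(np.array([1.0, 1.0, 2.0]), "fisher_jenks", k=3)


def _exhaustive_jenks_cost(x, k):
    """Best within-bin SSD over all contiguous partitions of sorted x."""
    import itertools

    x = np.sort(x)
    n = len(x)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        cost = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            grp = x[a:b]
            cost += ((grp - grp.mean()) ** 2).sum()
        best = min(best, cost)
    return best


class TestFisherJenks:
    def test_two_clear_clusters_split_exactly(self):
        breaks = fisher_jenks_breaks(np.array([1.0, 1, 1, 10, 10, 10]), 2)
        assert len(breaks) == 1 and breaks[0] == 1.0

    @pytest.mark.parametrize("k", [2, 3])
    def test_dp_matches_exhaustive_partition_search(self, k, rng):
        for _ in range(20):
            x = rng.uniform(0, 1, size=int(rng.integers(k + 1, 13)))
            assert fisher_jenks_cost(x, k) == pytest.approx(
                _exhaustive_jenks_cost(x, k), abs=1e-10
            )
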