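import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from medseq.dmr import (
    DMRTestConfig,
    adjust_pvalues,
    annotate_overlaps,
    call_region_dmrs,
    chi2_counts,
    chi2_counts_vec,
    normalized_fold,
    sliding_window_dmrs,
)
from medseq.reference import GeneModel, build_region_catalog
from medseq.regions import RegionCountMatrix, aggregate_regions
from medseq.scoring import GroupedCounts, SiteCountProfile
from .test_scoring import index_with_sites


def pearson_oracle(a, A, b, B):
    """Hand-coded Pearson chi-squared for [[a, A-a], [b, B-b]] from the
    textbook sum over cells of (observed - expected)^2 / expected."""
    table = np.array([[a, A - a], [b, B - b]], dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    return stat


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up: adjusted p for rank i is
    min over j >= i of m*p_(j)/j, capped at 1, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    for rank_index, idx in enumerate(order):
        candidates = [
            min(1.0, m * p[order[j]] / (j + 1)) for j in range(rank_index, m)
        ]
        adjusted[idx] = min(candidates)
    return adjusted


class TestChi2Counts:
    def test_identical_proportions_stat_zero(self):
        stat, p, degenerate = chi2_counts(10, 1000, 10, 1000)
        assert stat == 0.0 and p == 1.0 and not degenerate

    def test_matches_hand_pearson(self):
        stat, p, _ = chi2_counts(20, 1000, 5, 1000)
        assert stat == pytest.approx(pearson_oracle(20, 1000, 5, 1000), abs=1e-9)
        assert p == pytest.approx(chi2_dist.sf(stat, 1), abs=1e-12)

    def test_both_zero_degenerate(self):
        stat, p, degenerate = chi2_counts(0, 1000, 0, 1000)
        assert (stat, p, degenerate) == (0.0, 1.0, True)

    def test_count_above_total_fatal(self):
        with pytest.raises(ValueError):
            chi2_counts(20, 10, 5, 1000)

    def test_oracle_equivalence_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            A, B = rng.integers(10, 5000, size=2)
            a, b = rng.integers(0, A + 1), rng.integers(0, B + 1)
            if a + b == 0 or (A - a) + (B - b) == 0:
                continue
            stat, _, _ = chi2_counts(a, A, b, B)
            assert abs(stat - pearson_oracle(a, A, b, B)) < 1e-9

    def test_vectorized_equals_scalar(self):
        rng = np.random.default_rng(1)
        A, B = 4000, 6000
        a = rng.integers(0, 200, size=300)
        b = rng.integers(0, 200, size=300)
        stat_v, p_v, _ = chi2_counts_vec(a, A, b, B)
        for i in range(300):
            stat_s, p_s, _ = chi2_counts(a[i], A, b[i], B)
            assert stat_v[i] == pytest.approx(stat_s, abs=1e-9)
            assert p_v[i] == pytest.approx(p_s, abs=1e-12)


class TestAdjustPvalues:
    def test_single_pvalue_unchanged(self):
        for method in ("bonferroni", "bh"):
            assert adjust_pvalues([0.01], method).tolist() == [0.01]

    def test_bonferroni_multiplies_by_m(self):
        assert adjust_pvalues([0.01, 0.4], "bonferroni").tolist() == [0.02, 0.8]

    def test_bh_matches_bruteforce_enumeration(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert adjust_pvalues(p, "bh") == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_bh_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert adjust_pvalues(p, "bh") == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "bh")

    def test_bonferroni_dominates_bh(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, size=50)
        bonf = adjust_pvalues(p, "bonferroni")
        bh = adjust_pvalues(p, "bh")
        assert np.all(bonf >= bh - 1e-12)

    def test_bh_monotone_in_raw_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, size=100)
        adj = adjust_pvalues(p, "bh")
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestNormalizedFold:
    def test_equal_rates_fold_one(self):
        fold = normalized_fold(100, 1000, 100, 1000)
        assert fold.magnitude == pytest.approx(1.0) and fold.direction == "none"

    def test_doubling_at_large_counts(self):
        fold = normalized_fold(500, 100_000, 1000, 100_000)
        assert fold.magnitude == pytest.approx(2.0, rel=1e-3)
        assert fold.direction == "up"

    def test_zero_count_with_pseudocount(self):
        fold = normalized_fold(0, 1000, 20, 1000, pseudocount=0.5)
        assert fold.magnitude == pytest.approx(41.0)
        assert fold.direction == "up"


def two_group_matrix(counts_a, counts_b, total_a, total_b, n_sites=20, span=2000):
    region_ids = [f"r{i}" for i in range(len(counts_a))]
    index = pd.Index(region_ids, name="region_id")
    data = pd.DataFrame({"A": counts_a, "B": counts_b}, index=index, dtype=float)
    meta = pd.DataFrame(
        {
            "kind": "tss",
            "chrom": "chr1",
            "start": np.arange(len(counts_a)) * 10_000,
            "end": np.arange(len(counts_a)) * 10_000 + span,
            "n_sites": n_sites,
        },
        index=index,
    )
    return RegionCountMatrix("tss", data, meta, {"A": total_a, "B": total_b})


class TestCallRegionDmrs:
    def test_identical_groups_nothing_significant(self):
        counts = np.full(50, 40.0)
        matrix = two_group_matrix(counts, counts, 10_000, 10_000)
        records = call_region_dmrs(matrix, ("A", "B"))
        assert not any(r.significant for r in records)

    def test_planted_fivefold_region_recovered_with_smallest_p(self):
        rng = np.random.default_rng(5)
        n = 200
        counts_a = rng.poisson(40, size=n).astype(float)
        counts_b = rng.poisson(40, size=n).astype(float)
        counts_b[17] = rng.poisson(200)
        matrix = two_group_matrix(counts_a, counts_b, counts_a.sum(), counts_b.sum())
        records = call_region_dmrs(matrix, ("A", "B"))
        significant = [r for r in records if r.significant]
        assert [r.region_id for r in significant] == ["r17"]
        assert records[0].region_id == "r17"  # sorted by adjusted p
        assert records[0].direction == "up"

    def test_padj_floor_and_significance_invariant(self):
        rng = np.random.default_rng(6)
        counts_a = rng.poisson(40, size=100).astype(float)
        counts_b = rng.poisson(40, size=100).astype(float)
        matrix = two_group_matrix(counts_a, counts_b, 50_000, 50_000)
        config = DMRTestConfig(correction="bh", alpha=0.05, fold_threshold=2.0)
        for r in call_region_dmrs(matrix, ("A", "B"), config):
            assert r.p_adj >= r.p_raw - 1e-12
            assert r.significant == (
                r.p_adj <= 0.05 and r.fold_change >= 2.0 and not r.degenerate
            )

    def test_single_region_correction_is_identity(self):
        matrix = two_group_matrix([10.0], [50.0], 1000, 1000)
        (record,) = call_region_dmrs(matrix, ("A", "B"))
        assert record.p_adj == pytest.approx(record.p_raw)


def grouped_from_counts(index, counts_a, counts_b, total_a=None, total_b=None):
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    return GroupedCounts(
        ["A", "B"],
        {"A": counts_a, "B": counts_b},
        {
            "A": float(total_a if total_a is not None else counts_a.sum()),
            "B": float(total_b if total_b is not None else counts_b.sum()),
        },
    )


class WindowFixture:
    """Null background of strongly-covered sites plus a configurable run of
    differential sites; counts large enough that every run site is
    individually Bonferroni-significant."""

    def __init__(self, n_run, spacing, fold, n_background=40):
        positions = [1000 + 40 * i for i in range(n_background)]
        run_positions = [50_000 + spacing * i for i in range(n_run)]
        self.index = index_with_sites(positions + run_positions, length=200_000)
        base = np.full(n_background + n_run, 1000.0)
        counts_a = base.copy()
        counts_b = base.copy()
        counts_b[n_background:] = 1000.0 * fold
        total = 1_000_000.0
        self.grouped = grouped_from_counts(self.index, counts_a, counts_b, total, total)


class TestSlidingWindowDmrs:
    def test_twelve_site_600bp_fourfold_run_is_one_dmr(self):
        fixture = WindowFixture(n_run=12, spacing=54, fold=4.0)  # span 595
        records = sliding_window_dmrs(fixture.grouped, fixture.index, ("A", "B"))
        assert len(records) == 1
        record = records[0]
        assert record.n_sites == 12 and record.direction == "up"
        assert record.span_bp >= 100 and record.fold_change >= 2.0

    def test_nine_significant_sites_no_dmr(self):
        fixture = WindowFixture(n_run=9, spacing=54, fold=4.0)
        assert sliding_window_dmrs(fixture.grouped, fixture.index, ("A", "B")) == []

    def test_ten_sites_80bp_span_no_dmr(self):
        fixture = WindowFixture(n_run=10, spacing=8, fold=4.0)  # span 73 < 100
        assert sliding_window_dmrs(fixture.grouped, fixture.index, ("A", "B")) == []

    def test_subthreshold_fold_no_dmr(self):
        fixture = WindowFixture(n_run=10, spacing=54, fold=1.9)
        assert sliding_window_dmrs(fixture.grouped, fixture.index, ("A", "B")) == []

    def test_direction_change_breaks_run(self):
        positions = [50_000 + 54 * i for i in range(20)]
        index = index_with_sites(positions, length=200_000)
        counts_a = np.full(20, 1000.0)
        counts_b = np.full(20, 4000.0)
        counts_b[9] = 250.0  # opposite direction in the middle
        grouped = grouped_from_counts(index, counts_a, counts_b, 1e6, 1e6)
        records = sliding_window_dmrs(grouped, index, ("A", "B"))
        assert all(r.n_sites < 20 for r in records)
        assert len(records) == 1 and records[0].n_sites == 10  # sites 10..19

    def test_every_reported_window_satisfies_all_thresholds(self):
        fixture = WindowFixture(n_run=25, spacing=30, fold=3.0)
        config = DMRTestConfig(min_sites=10, min_span_bp=100, fold_threshold=2.0)
        for record in sliding_window_dmrs(fixture.grouped, fixture.index, ("A", "B"), config):
            assert record.n_sites >= 10
            assert record.span_bp >= 100
            assert record.fold_change >= 2.0

    def test_empty_site_index_empty_result(self):
        index = index_with_sites([])
        grouped = grouped_from_counts(index, [], [], 10.0, 10.0)
        assert sliding_window_dmrs(grouped, index, ("A", "B")) == []


class TestStatisticalProperties:
    """Derandomized property tests of the statistical primitives."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_bh_always_matches_bruteforce(self, p):
        assert adjust_pvalues(p, "bh") == pytest.approx(bh_oracle(p), abs=1e-12)

    @given(
        st.integers(100, 5000), st.integers(100, 5000),
        st.integers(0, 100), st.integers(0, 100),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_chi2_symmetric_in_group_order(self, A, B, a, b):
        stat_ab, p_ab, _ = chi2_counts(a, A, b, B)
        stat_ba, p_ba, _ = chi2_counts(b, B, a, A)
        assert stat_ab == pytest.approx(stat_ba, abs=1e-9)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    @given(
        st.integers(100, 5000), st.integers(100, 5000),
        st.integers(0, 100), st.integers(0, 100),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_fold_magnitude_invariant_to_group_swap(self, A, B, a, b):
        forward = normalized_fold(a, A, b, B)
        backward = normalized_fold(b, B, a, A)
        assert forward.magnitude == pytest.approx(backward.magnitude, rel=1e-12)
        swap = {"up": "down", "down": "up", "none": "none"}
        assert backward.direction == swap[forward.direction]


class TestAnnotateOverlaps:
    def make_catalog(self):
        genes = [GeneModel("g1", "chr1", "+", 5000, 9000)]
        islands = [("cgi1", "chr1", 5800, 6500)]
        return build_region_catalog(genes, islands, {"chr1": 100_000})

    def dmr_at(self, start, end):
        from medseq.dmr import DMRRecord

        return DMRRecord(
            region_id=f"chr1:{start}-{end}", kind="window", chrom="chr1",
            start=start, end=end, count_a=1, total_a=10, count_b=5, total_b=10,
            fold_change=5.0, direction="up", chi2_stat=1.0, p_raw=0.1, p_adj=0.1,
            significant=False, n_sites=10, span_bp=end - start,
        )

    def test_dmr_inside_tss_window(self):
        catalog = self.make_catalog()
        (dmr,) = annotate_overlaps([self.dmr_at(4100, 4300)], catalog)
        assert dmr.overlaps == {"tss": ["g1"]}

    def test_dmr_in_gene_desert_empty(self):
        catalog = self.make_catalog()
        (dmr,) = annotate_overlaps([self.dmr_at(50_000, 50_200)], catalog)
        assert dmr.overlaps == {}

    def test_dmr_spanning_tss_and_island(self):
        catalog = self.make_catalog()
        (dmr,) = annotate_overlaps([self.dmr_at(5900, 6100)], catalog)
        assert set(dmr.overlaps) == {"tss", "cpg_island", "genebody"}
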