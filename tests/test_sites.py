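"""Site calling, overlap algebra, Venn partitions, and length summaries.

The independent oracle for region calling literally re-scans: it grows seed
runs by absorbing any in-range qualifying window, one at a time, until
nothing changes, then merges touching regions -- an exhaustive fixpoint
implementation kept deliberately naive.
"""

import numpy as np
import pandas as pd
import pytest

from dhrcall import (
    AnalysisParams,
    GenomeLayout,
    SiteSet,
    call_conserved_sites,
    call_dhrs,
    call_individual_sites,
    intersect_core_sites,
    length_summary,
    make_windows,
    overlap_site_sets,
    sweep_dhr_thresholds,
    window_venn,
)
from dhrcall.differential import DifferentialResult


def diff_from_p(p, window_size=100, chrom="chr1"):
    p = np.asarray(p, dtype=float)
    layout = GenomeLayout((chrom,), (len(p) * window_size,))
    tiling = make_windows(layout, window_size)
    z = np.zeros(len(p))
    return DifferentialResult(tiling, "control", "exposure", p, z, z, z, phi=0.0)


def rescan_oracle(starts, ends, qualifying, seed, max_dist, strict=True):
    """Exhaustive extension-to-fixpoint + merge; returns (lo, hi) index pairs."""
    n = len(starts)
    regions = []
    i = 0
    while i < n:
        if seed[i]:
            j = i
            while j + 1 < n and seed[j + 1]:
                j += 1
            regions.append([i, j])
            i = j + 1
        else:
            i += 1
    changed = bool(regions)
    while changed:
        changed = False
        for reg in regions:
            grew = True
            while grew:
                grew = False
                for w in range(n):
                    if not qualifying[w] or reg[0] <= w <= reg[1]:
                        continue
                    gap = starts[reg[0]] - ends[w] if w < reg[0] else starts[w] - ends[reg[1]]
                    within = gap < max_dist if strict else gap <= max_dist
                    if within:
                        reg[0] = min(reg[0], w)
                        reg[1] = max(reg[1], w)
                        grew = changed = True
        regions.sort()
        merged = [regions[0]]
        for r in regions[1:]:
            if r[0] <= merged[-1][1] + 1:  # overlap or touch
                merged[-1][1] = max(merged[-1][1], r[1])
            else:
                merged.append(r)
        regions = merged
    return [(lo, hi) for lo, hi in regions]


def assert_fixpoint(sites: SiteSet, tiling, qualifying, max_dist, strict=True):
    """No qualifying window may remain within range of any final edge."""
    for chrom in tiling.layout.names:
        sl = tiling.chrom_slice(chrom)
        q = np.flatnonzero(qualifying[sl])
        starts, ends = tiling.starts(chrom), tiling.ends(chrom)
        sub = sites.sites[sites.sites["chrom"] == chrom]
        for _, row in sub.iterrows():
            for w in q:
                if starts[w] >= row["start"] and ends[w] <= row["end"]:
                    continue
                gap = (
                    row["start"] - ends[w]
                    if ends[w] <= row["start"]
                    else starts[w] - row["end"]
                )
                assert gap >= 0, "qualifying window partially outside a site"
                inside = gap < max_dist if strict else gap <= max_dist
                assert not inside, f"qualifying window within {max_dist} bp of an edge"


class TestCallDhrs:
    def setup_method(self):
        self.params = AnalysisParams(dhr_p_threshold=1e-7)

    def test_no_significant_windows_empty_set(self):
        sites = call_dhrs(diff_from_p([1.0] * 30), self.params)
        assert len(sites) == 0

    def test_isolated_seed_no_extension(self):
        p = np.full(20, 0.5)
        p[0] = 1e-8
        sites = call_dhrs(diff_from_p(p), self.params)
        assert len(sites) == 1
        row = sites.sites.iloc[0]
        assert (row["start"], row["end"], row["n_sig_windows"]) == (0, 100, 1)

    def test_bridged_seeds_merge_through_sub_threshold_window(self):
        p = np.full(20, 0.5)
        p[0] = 1e-8
        p[1] = 0.05
        p[2] = 1e-8
        sites = call_dhrs(diff_from_p(p), self.params)
        assert len(sites) == 1
        row = sites.sites.iloc[0]
        assert (row["start"], row["end"], row["n_sig_windows"]) == (0, 300, 2)

    def test_extension_chains_across_qualifying_run(self):
        # p<0.1 windows each within 1000 bp of the growing edge chain outward
        p = np.full(40, 0.5)
        p[10] = 1e-9
        for i in (12, 18, 25):  # gaps 100, 500, 600 bp between qualifying windows
            p[i] = 0.05
        sites = call_dhrs(diff_from_p(p), self.params)
        assert len(sites) == 1
        row = sites.sites.iloc[0]
        assert (row["start"], row["end"]) == (1_000, 2_600)

    def test_strict_edge_rule_excludes_exact_1000bp_gap(self):
        p = np.full(30, 0.5)
        p[0] = 1e-9
        p[11] = 0.05  # gap = start(11) - end(0) = 1000 exactly
        strict = call_dhrs(diff_from_p(p), AnalysisParams(edge_rule="strict"))
        closed = call_dhrs(diff_from_p(p), AnalysisParams(edge_rule="closed"))
        assert strict.sites.iloc[0]["end"] == 100
        assert closed.sites.iloc[0]["end"] == 1_200

    def test_length_mismatch_rejected(self):
        d = diff_from_p([0.5] * 10)
        with pytest.raises(ValueError):
            DifferentialResult(
                d.tiling, "control", "exposure",
                np.full(5, 0.5), np.zeros(10), np.zeros(10), np.zeros(10), 0.0,
            )

    def test_matches_rescan_oracle_on_random_genomes(self):
        rng = np.random.default_rng(42)
        params = AnalysisParams(dhr_p_threshold=0.01, edge_p=0.1, edge_dist=350)
        for _ in range(60):
            n = int(rng.integers(5, 100))
            p = rng.random(n)
            p[rng.random(n) < 0.15] = 0.05
            p[rng.random(n) < 0.1] = 1e-3
            d = diff_from_p(p)
            sites = call_dhrs(d, params)
            tiling = d.tiling
            starts, ends = tiling.starts("chr1"), tiling.ends("chr1")
            expected = rescan_oracle(starts, ends, p < 0.1, p < 0.01, 350)
            got = [(int(r["start"]), int(r["end"])) for _, r in sites.sites.iterrows()]
            assert got == [(int(starts[lo]), int(ends[hi])) for lo, hi in expected]
            assert_fixpoint(sites, tiling, p < 0.1, 350)
            # every seed window lies inside exactly one site
            for w in np.flatnonzero(p < 0.01):
                inside = [
                    (starts[w] >= r["start"]) and (ends[w] <= r["end"])
                    for _, r in sites.sites.iterrows()
                ]
                assert sum(inside) == 1

    def test_seed_monotonicity_in_threshold(self):
        rng = np.random.default_rng(43)
        p = rng.random(200) ** 4
        d = diff_from_p(p)
        loose = call_dhrs(d, AnalysisParams(dhr_p_threshold=1e-2), p_threshold=1e-2)
        tight = call_dhrs(d, AnalysisParams(dhr_p_threshold=1e-2), p_threshold=1e-4)
        # every tight site is covered by a loose site
        for _, r in tight.sites.iterrows():
            sub = loose.sites[loose.sites["chrom"] == r["chrom"]]
            assert ((sub["start"] <= r["start"]) & (sub["end"] >= r["end"])).any()


class TestSweep:
    def test_single_threshold_counts(self):
        p = np.full(20, 0.5)
        p[0] = 1e-8
        p[1] = 0.05
        p[2] = 1e-8
        table = sweep_dhr_thresholds(diff_from_p(p), [1e-7], AnalysisParams())
        assert table.iloc[0]["all_window_count"] == 1
        assert table.iloc[0]["multiple_window_count"] == 1

    def test_counts_monotone_and_bounded(self):
        rng = np.random.default_rng(44)
        p = rng.random(500) ** 6
        table = sweep_dhr_thresholds(
            diff_from_p(p), [1e-4, 1e-5, 1e-6, 1e-7, 1e-8], AnalysisParams()
        )
        allc = table["all_window_count"].to_numpy()
        multi = table["multiple_window_count"].to_numpy()
        assert np.all(np.diff(allc) <= 0)  # tighter cutoff, fewer DHRs
        assert np.all(multi <= allc)

    def test_flat_pvalues_all_zero(self):
        table = sweep_dhr_thresholds(diff_from_p([1.0] * 50), [1e-4, 1e-6], AnalysisParams())
        assert (table[["all_window_count", "multiple_window_count"]] == 0).all().all()

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(ValueError):
            sweep_dhr_thresholds(diff_from_p([1.0] * 5), [], AnalysisParams())


class TestDepthSites:
    def test_below_threshold_everywhere_empty(self, matrix_factory):
        m = matrix_factory(np.full((30, 2), 100), ["g", "g"])
        assert len(call_conserved_sites(m, "g", AnalysisParams())) == 0

    def test_adjacent_qualifying_windows_form_one_site(self, matrix_factory):
        counts = np.full((30, 2), 10)
        counts[5:8] = 200
        m = matrix_factory(counts, ["g", "g"])
        sites = call_conserved_sites(m, "g", AnalysisParams())
        assert len(sites) == 1
        row = sites.sites.iloc[0]
        assert (row["start"], row["end"]) == (500, 800)
        assert row["score"] >= 150

    def test_gap_under_1kb_merges_gap_over_1kb_splits(self, matrix_factory):
        counts = np.full((40, 1), 10)
        counts[[5, 14]] = 200  # gap = 800 bp
        m = matrix_factory(counts, ["g"])
        merged = call_individual_sites(m, "s0", AnalysisParams())
        assert len(merged) == 1
        assert (merged.sites.iloc[0]["start"], merged.sites.iloc[0]["end"]) == (500, 1_500)

        counts = np.full((40, 1), 10)
        counts[[5, 18]] = 200  # gap = 1200 bp
        m = matrix_factory(counts, ["g"])
        split = call_individual_sites(m, "s0", AnalysisParams())
        assert len(split) == 2

    def test_requires_threshold_in_all_group_samples(self, matrix_factory):
        counts = np.full((10, 3), 10)
        counts[4] = (200, 200, 100)  # one sample below threshold
        m = matrix_factory(counts, ["g"] * 3)
        assert len(call_conserved_sites(m, "g", AnalysisParams())) == 0

    def test_lower_threshold_gives_superset(self, matrix_factory):
        rng = np.random.default_rng(45)
        counts = rng.poisson(60, (300, 1)) + rng.integers(0, 200, (300, 1))
        m = matrix_factory(counts, ["g"])
        hi = call_individual_sites(m, "s0", AnalysisParams(depth_threshold=150))
        lo = call_individual_sites(m, "s0", AnalysisParams(depth_threshold=25))
        for _, r in hi.sites.iterrows():
            sub = lo.sites[lo.sites["chrom"] == r["chrom"]]
            assert ((sub["start"] <= r["start"]) & (sub["end"] >= r["end"])).any()

    def test_matches_rescan_oracle(self, matrix_factory):
        rng = np.random.default_rng(46)
        for _ in range(40):
            n = int(rng.integers(5, 100))
            counts = rng.integers(0, 300, (n, 2))
            m = matrix_factory(counts, ["g", "g"])
            sites = call_conserved_sites(m, "g", AnalysisParams())
            qual = (counts >= 150).all(axis=1)
            starts = m.tiling.starts("chrT")
            ends = m.tiling.ends("chrT")
            expected = rescan_oracle(starts, ends, qual, qual, 1_000)
            got = [(int(r["start"]), int(r["end"])) for _, r in sites.sites.iterrows()]
            assert got == [(int(starts[lo]), int(ends[hi])) for lo, hi in expected]
            assert_fixpoint(sites, m.tiling, qual, 1_000)

    def test_empty_group_rejected(self, matrix_factory):
        m = matrix_factory(np.ones((5, 1), dtype=int), ["g"])
        with pytest.raises(KeyError):
            call_conserved_sites(m, "nope", AnalysisParams())


class TestCoreIntersection:
    def _sets(self, *interval_lists):
        return [
            SiteSet.from_intervals("conserved", iv, provenance=f"g{i}")
            for i, iv in enumerate(interval_lists)
        ]

    def test_identical_sets_core_is_the_set(self):
        iv = [("chr1", 0, 500), ("chr1", 1_000, 1_600)]
        sets = self._sets(*([iv] * 6))
        core = intersect_core_sites(sets, representative="g0")
        assert len(core) == 2

    def test_any_empty_set_empties_core(self):
        sets = self._sets([("chr1", 0, 500)], [])
        assert len(intersect_core_sites(sets, representative="g0")) == 0

    def test_representative_intervals_reported_verbatim(self):
        sets = self._sets([("chr1", 0, 1_000)], [("chr1", 900, 2_000)], [("chr1", 999, 5_000)])
        core = intersect_core_sites(sets, representative="g0")
        assert [(r["start"], r["end"]) for _, r in core.sites.iterrows()] == [(0, 1_000)]

    def test_idempotent_against_same_sets(self):
        sets = self._sets(
            [("chr1", 0, 1_000), ("chr2", 0, 300)],
            [("chr1", 500, 1_500)],
        )
        core = intersect_core_sites(sets, representative="g0")
        again = intersect_core_sites([core] + sets[1:], representative="g0")
        pd.testing.assert_frame_equal(core.sites, again.sites)

    def test_unknown_representative_rejected(self):
        sets = self._sets([("chr1", 0, 100)], [("chr1", 0, 100)])
        with pytest.raises(KeyError):
            intersect_core_sites(sets, representative="missing")

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            intersect_core_sites(self._sets([("chr1", 0, 100)]), representative="g0")


class TestVenn:
    def test_identical_sets_fully_common(self):
        w = np.array([1, 5, 9])
        out = window_venn([w] * 5)
        assert out["fraction_common"] == 1.0

    def test_disjoint_sets(self):
        out = window_venn([np.array([0]), np.array([1]), np.array([2])])
        assert out["fraction_common"] == 0.0
        assert out["intersection"] == 0

    def test_three_set_partition(self):
        out = window_venn(
            [np.array([1, 2]), np.array([1]), np.array([1, 3])], labels=["A", "B", "C"]
        )
        assert out["intersection"] == 1
        assert out["union"] == 3
        assert out["fraction_common"] == pytest.approx(1 / 3)
        assert out["region_counts"]["A&B&C"] == 1
        assert out["region_counts"]["A"] == 1  # window 2 only in A
        assert out["region_counts"]["A&C"] == 0

    def test_set_count_guard(self):
        with pytest.raises(ValueError):
            window_venn([np.array([0])])
        with pytest.raises(ValueError):
            window_venn([np.array([0])] * 8)


class TestOverlapCounts:
    def test_identical_sets(self):
        a = SiteSet.from_intervals("DHR", [("chr1", 0, 100), ("chr1", 500, 900)])
        out = overlap_site_sets(a, a)
        assert out["a_shared"] == 2 and out["a_only"] == 0

    def test_disjoint_sets(self):
        a = SiteSet.from_intervals("DHR", [("chr1", 0, 100)])
        b = SiteSet.from_intervals("DHR", [("chr2", 0, 100)])
        out = overlap_site_sets(a, b)
        assert out["a_shared"] == 0 and out["b_only"] == 1

    def test_asymmetric_counts(self):
        a = SiteSet.from_intervals("DHR", [("chr1", 0, 500)])
        b = SiteSet.from_intervals("DHR", [("chr1", 400, 600), ("chr1", 700, 800)])
        out = overlap_site_sets(a, b)
        assert out == {
            "a_total": 1, "b_total": 2,
            "a_shared": 1, "b_shared": 1,
            "a_only": 0, "b_only": 1,
        }


class TestLengthSummary:
    def test_single_small_site(self):
        s = SiteSet.from_intervals("DHR", [("chr1", 0, 100)])
        out = length_summary(s, [0, 1, 5, np.inf])
        assert list(out["count"]) == [1, 0, 0]

    def test_left_closed_bins(self):
        s = SiteSet.from_intervals(
            "DHR", [("chr1", 0, 1_000), ("chr1", 5_000, 9_000), ("chr1", 20_000, 32_000)]
        )
        out = length_summary(s, [0, 1, 5, np.inf])
        assert list(out["count"]) == [0, 2, 1]  # exactly 1.0 kb lands in [1, 5)

    def test_empty_set_and_bad_edges(self):
        empty = SiteSet.empty("DHR")
        assert length_summary(empty, [0, 1, np.inf])["count"].sum() == 0
        with pytest.raises(ValueError):
            length_summary(empty, [1, 0])
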