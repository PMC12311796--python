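"""SE activity/G4-richness classification and colocalization profiling."""

import numpy as np
import pytest
from scipy import stats

from g4se.genome import GenomeLayout, Interval, IntervalSet
from g4se.superenhancers import (
    SERecord,
    classify_activity,
    classify_g4_richness,
    colocalization_profile,
    compare_coverage,
    compute_coverage,
    rank_ses_for_motif_search,
)


@pytest.fixture
def layout():
    return GenomeLayout(("chr1",), (100_000_000,))


def iset(layout, *spans):
    return IntervalSet([Interval("chr1", s, e) for s, e in spans], layout)


class TestActivityTruthTable:
    """Catalog membership x CAGE status -> activity label, all 8 cases."""

    def test_truth_table(self, layout):
        # target catalog: A (CAGE+), B (CAGE-), E (CAGE+, also in other),
        #                 F (CAGE-, also in other)
        # other-only:     C (CAGE+), D (CAGE-)
        target = iset(layout, (1000, 2000), (3000, 4000), (9000, 10_000),
                      (11_000, 12_000))
        other = iset(layout, (5000, 6000), (7000, 8000), (9000, 10_000),
                     (11_000, 12_000))
        cage = iset(layout, (1500, 1600), (5500, 5600), (9500, 9600))
        records = classify_activity(
            {"target": target, "other": other}, cage, "target"
        )
        by_start = {r.interval.start: r for r in records}
        assert by_start[1000].activity == "active"
        assert by_start[3000].activity == "poised"
        assert by_start[5000].activity == "not_applicable"
        assert by_start[7000].activity == "repressed"
        # present in target AND other: classified by the target-cell rule
        assert by_start[9000].activity == "active"
        assert by_start[11_000].activity == "poised"
        assert by_start[9000].present_in == frozenset({"target", "other"})
        assert by_start[7000].present_in == frozenset({"other"})

    def test_every_se_gets_exactly_one_label(self, layout):
        rng = np.random.default_rng(0)
        starts_t = np.arange(0, 500_000, 5000)
        starts_o = np.arange(2500, 500_000, 7000)
        target = iset(layout, *[(int(s), int(s) + 2000) for s in starts_t])
        other = iset(layout, *[(int(s), int(s) + 2000) for s in starts_o])
        cage_pos = rng.choice(starts_t, size=30, replace=False)
        cage = iset(layout, *[(int(s) + 100, int(s) + 200) for s in cage_pos])
        records = classify_activity({"t": target, "o": other}, cage, "t")
        labels = {"active", "poised", "repressed", "not_applicable"}
        assert all(r.activity in labels for r in records)
        # target intervals all present; none double-counted
        assert sum(1 for r in records if "t" in r.present_in) == len(target)

    def test_empty_target_catalog_rejected(self, layout):
        with pytest.raises(ValueError):
            classify_activity(
                {"t": IntervalSet([], layout)}, IntervalSet([], layout), "t"
            )

    def test_unknown_target_cell_rejected(self, layout):
        with pytest.raises(ValueError, match="target cell"):
            classify_activity({"t": iset(layout, (0, 10))},
                              IntervalSet([], layout), "x")


def make_records(layout, n, se_len=10_000, activity="active"):
    return [
        SERecord(
            interval=Interval("chr1", i * (se_len + 100), i * (se_len + 100) + se_len),
            present_in=frozenset({"t"}),
            cage_positive=activity == "active",
            activity=activity,
        )
        for i in range(n)
    ]


class TestG4Richness:
    def test_zero_peaks_is_g4_free(self, layout):
        records = make_records(layout, 8)
        bg4 = iset(layout, *[(r.interval.start + 10, r.interval.start + 110)
                             for r in records[:4]])
        out = classify_g4_richness(records, bg4)
        assert all(r.g4_class == "g4_free" for r in out[4:])
        assert all(r.g4_class != "g4_free" for r in out[:4])

    def test_distinct_frequencies_give_exactly_quarter(self, layout):
        records = make_records(layout, 100)
        peaks = []
        for i, r in enumerate(records):
            # i+1 distinct peak counts per SE of equal length
            for k in range(i + 1):
                peaks.append((r.interval.start + 20 * k, r.interval.start + 20 * k + 10))
        out = classify_g4_richness(records, iset(layout, *peaks))
        assert sum(1 for r in out if r.g4_class == "g4_rich") == 25

    def test_all_tied_nonzero_all_rich(self, layout):
        records = make_records(layout, 8)
        bg4 = iset(layout, *[(r.interval.start + 10, r.interval.start + 110)
                             for r in records])
        out = classify_g4_richness(records, bg4)
        assert all(r.g4_class == "g4_rich" for r in out)

    def test_rich_and_free_disjoint_within_active_poised(self, layout):
        records = make_records(layout, 20) + make_records(layout, 0)
        rng = np.random.default_rng(1)
        peaks = []
        for r in records:
            for k in range(int(rng.integers(0, 5))):
                peaks.append((r.interval.start + 30 * k, r.interval.start + 30 * k + 10))
        out = classify_g4_richness(records, iset(layout, *peaks))
        rich = {id(r) for r in out if r.g4_class == "g4_rich"}
        free = {id(r) for r in out if r.g4_class == "g4_free"}
        assert not rich & free
        assert all(r.peak_counts["BG4"] > 0 for r in out if id(r) in rich)

    def test_too_few_records_rejected(self, layout):
        with pytest.raises(ValueError, match="quartile"):
            classify_g4_richness(make_records(layout, 3), iset(layout, (0, 10)))


class TestCompareCoverage:
    def rec(self, layout, start, cov):
        r = SERecord(Interval("chr1", start, start + 1000), frozenset(), False,
                     "active")
        r.coverage["DHS"] = cov
        return r

    def test_exact_p_for_separated_groups(self, layout):
        a = [self.rec(layout, i * 2000, v) for i, v in enumerate([0.1, 0.2, 0.3])]
        b = [self.rec(layout, 50_000 + i * 2000, v)
             for i, v in enumerate([0.4, 0.5, 0.6])]
        out = compare_coverage(a, b, "DHS")
        assert out["U"] == 0.0
        assert out["p"] == pytest.approx(0.1)  # 2/C(6,3) = 2/20
        assert out["method"] == "exact"

    def test_identical_groups_p_one(self, layout):
        a = [self.rec(layout, i * 2000, v) for i, v in enumerate([0.1, 0.2, 0.3])]
        out = compare_coverage(a, a, "DHS")
        assert out["p"] == pytest.approx(1.0)

    def test_empty_group_rejected(self, layout):
        a = [self.rec(layout, 0, 0.5)]
        with pytest.raises(ValueError):
            compare_coverage(a, [], "DHS")

    def test_power_against_planted_shift(self, layout):
        """A +0.1 coverage shift at n=100/group is detected at alpha=0.05 in
        >= 90% of seeds."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = [self.rec(layout, i * 2000, v)
                 for i, v in enumerate(rng.beta(2, 8, size=100))]
            b = [self.rec(layout, 500_000 + i * 2000, v)
                 for i, v in enumerate(np.clip(rng.beta(2, 8, size=100) + 0.1, 0, 1))]
            if compare_coverage(a, b, "DHS")["p"] < 0.05:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_null_p_values_are_uniform(self, layout):
        """Under identical distributions the U-test p-values are ~uniform."""
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(1000):
            a = [self.rec(layout, i * 2000, v)
                 for i, v in enumerate(rng.random(12))]
            b = [self.rec(layout, 500_000 + i * 2000, v)
                 for i, v in enumerate(rng.random(12))]
            pvals.append(compare_coverage(a, b, "DHS")["p"])
        # exact-test p-values are discrete and conservative; KS on the
        # continuous-corrected values must not reject at alpha=0.01
        assert stats.kstest(pvals, "uniform").statistic < 0.08

    def test_coverage_computation_feeds_records(self, layout):
        records = make_records(layout, 4)
        dhs = iset(layout, (records[0].interval.start,
                            records[0].interval.start + 2100))
        compute_coverage(records, {"DHS": dhs})
        assert records[0].coverage["DHS"] == pytest.approx(0.21)
        assert records[1].coverage["DHS"] == 0.0


class TestColocalizationProfile:
    def test_centered_peak_has_zero_offset(self, layout):
        anchors = iset(layout, (10_000, 10_200))  # center 10100
        marks = {"DHS": iset(layout, (10_050, 10_150))}  # center 10100
        prof = colocalization_profile(anchors, marks, window=1000, bin_size=50)
        assert prof.offsets["DHS"].tolist() == [0]
        assert prof.frac_within("DHS", 0) == 1.0

    def test_flank_planted_marks_avoid_center(self, layout):
        from g4se.simulate import _offset_peaks

        rng = np.random.default_rng(0)
        anchor_ivs = [Interval("chr1", s, s + 200)
                      for s in range(10_000, 900_000, 3000)]
        anchors = IntervalSet(anchor_ivs, layout)
        h3k = _offset_peaks(anchor_ivs, (200, 500), 200, layout, rng)
        dhs = _offset_peaks(anchor_ivs, (0, 100), 200, layout, rng)
        prof = colocalization_profile(anchors, {"H3K27ac": h3k, "DHS": dhs},
                                      window=1000, bin_size=50)
        assert prof.frac_within("H3K27ac", 100) <= 0.02
        assert prof.frac_within("DHS", 100) >= 0.95

    def test_window_must_be_multiple_of_bin(self, layout):
        anchors = iset(layout, (0, 100))
        with pytest.raises(ValueError):
            colocalization_profile(anchors, {}, window=1000, bin_size=300)

    def test_no_anchors_rejected(self, layout):
        with pytest.raises(ValueError, match="anchors"):
            colocalization_profile(IntervalSet([], layout), {})


class TestRankForMotifSearch:
    def test_single_category_top_k(self, layout):
        records = make_records(layout, 10)
        peaks = []
        for i, r in enumerate(records):
            for k in range(i):
                peaks.append((r.interval.start + 25 * k, r.interval.start + 25 * k + 10))
        sel = rank_ses_for_motif_search(records, {"BG4": iset(layout, *peaks)}, k=5)
        # frequency and count orderings coincide (equal lengths): union = top 5
        assert len(sel) == 5
        starts = {r.interval.start for r in sel}
        assert starts == {r.interval.start for r in records[5:]}

    def test_union_deduplicates(self, layout):
        records = make_records(layout, 6)
        peaks = iset(layout, (records[0].interval.start,
                              records[0].interval.start + 50))
        sel = rank_ses_for_motif_search(
            records, {"BG4": peaks, "G4seq": peaks}, k=5
        )
        assert len(sel) == len({id(r) for r in sel})
        # every category yields the same (tie-stable) top-5: union is 5, not 20
        assert len(sel) == 5

    def test_matches_sort_and_merge_oracle(self, layout):
        rng = np.random.default_rng(3)
        records = make_records(layout, 15)
        sets = {}
        for name in ("BG4", "G4seq"):
            peaks = []
            for r in records:
                for k in range(int(rng.integers(0, 6))):
                    peaks.append((r.interval.start + 40 * k,
                                  r.interval.start + 40 * k + 20))
            sets[name] = iset(layout, *peaks)
        sel = rank_ses_for_motif_search(records, sets, k=3)
        expected_ids = set()
        for name in sets:
            for key in ("frequency", "count"):
                stat = [
                    (r.peak_counts[name] / (len(r.interval) / 1000)
                     if key == "frequency" else r.peak_counts[name])
                    for r in records
                ]
                top = sorted(range(len(records)), key=lambda i: -stat[i])[:3]
                expected_ids |= {id(records[i]) for i in top}
        # oracle must agree on the selected identity set when ordering keys
        # are unambiguous (distinct statistic values within each category)
        assert {id(r) for r in sel} == expected_ids
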