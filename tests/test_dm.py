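import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nimbl import (
    BetaDataset,
    GroupDesign,
    GroupExhaustedError,
    NimblError,
    detect_dm,
    filter_sites,
    gene_summary,
    group_gap,
    islands_only,
    mask_and_test,
    score,
    wilcoxon_comparator,
)
from nimbl.synth import SimConfig, simulate

from conftest import make_annotation


def nanlike(frame):
    return pd.DataFrame(np.nan, index=frame.index, columns=frame.columns)


def two_group_design(n1, n2, m=(0, 0), ranges=None):
    a = {f"a{i}": "A" for i in range(n1)} | {f"b{i}": "B" for i in range(n2)}
    return GroupDesign(("A", "B"), a, mask_limits=m, range_constraints=ranges)


def site(values_a, values_b):
    return pd.Series(
        {f"a{i}": v for i, v in enumerate(values_a)}
        | {f"b{i}": v for i, v in enumerate(values_b)}
    )


# ---------------------------------------------------------------------------
# group_gap
# ---------------------------------------------------------------------------

class TestGroupGap:
    def test_non_overlapping_groups(self):
        d = two_group_design(2, 2)
        assert group_gap(site([0.1, 0.2], [0.5, 0.6]), d) == pytest.approx(0.3)

    def test_overlap_is_negative(self):
        d = two_group_design(2, 2)
        assert group_gap(site([0.1, 0.6], [0.5, 0.9]), d) == pytest.approx(-0.1)

    def test_masking_recomputes_gap(self):
        d = two_group_design(2, 2)
        gap = group_gap(site([0.1, 0.6], [0.5, 0.9]), d, masked={"a1"})
        assert gap == pytest.approx(0.4)

    def test_group_exhausted_raises(self):
        d = two_group_design(2, 2)
        with pytest.raises(GroupExhaustedError):
            group_gap(site([np.nan, np.nan], [0.5, 0.9]), d)


# ---------------------------------------------------------------------------
# score
# ---------------------------------------------------------------------------

class TestScore:
    @pytest.mark.parametrize(
        "gap,median_diff,expected",
        [(0.4, 0.5, 0.3), (0.6, 0.6, 0.6)],
    )
    def test_known_values(self, gap, median_diff, expected):
        assert score(gap, median_diff) == pytest.approx(expected)

    def test_composed_from_gap_and_medians(self):
        d = two_group_design(2, 2)
        s = site([0.1, 0.2], [0.5, 0.6])
        gap = group_gap(s, d)
        median_diff = abs(
            np.median([0.5, 0.6]) - np.median([0.1, 0.2])
        )
        assert score(gap, median_diff) == pytest.approx(0.2)

    def test_median_diff_below_gap_is_a_caller_bug(self):
        with pytest.raises(NimblError, match="median_diff"):
            score(0.5, 0.4)

    @settings(max_examples=300, derandomize=True)
    @given(st.floats(1e-6, 1.0), st.floats(0.0, 1.0))
    def test_algebraic_identity(self, gap, extra):
        """score == 2*gap - median_diff for every valid pair."""
        median_diff = min(gap + extra * (1 - gap), 1.0)
        assert score(gap, median_diff) == 2.0 * gap - median_diff
        assert score(gap, median_diff) <= gap + 1e-15


# ---------------------------------------------------------------------------
# mask_and_test
# ---------------------------------------------------------------------------

class TestMaskAndTest:
    def test_hand_traced_iteration(self):
        # medians 0.15 / 0.65; A's 0.55 is most distant (0.40) -> masked;
        # new gap 0.60 - 0.15 = 0.45 >= 0.3
        d = two_group_design(3, 3, m=(1, 1))
        passed, masked, gap = mask_and_test(
            site([0.10, 0.15, 0.55], [0.60, 0.65, 0.70]), d, d=0.3
        )
        assert passed
        assert masked == {"A": ["a2"], "B": []}
        assert gap == pytest.approx(0.45)

    def test_separated_groups_pass_with_zero_masking(self):
        d = two_group_design(2, 2, m=(0, 0))
        passed, masked, gap = mask_and_test(site([0.1, 0.2], [0.5, 0.6]), d, d=0.1)
        assert passed and masked == {"A": [], "B": []}
        assert gap == pytest.approx(0.3)

    def test_overlap_without_masking_fails(self):
        d = two_group_design(2, 2, m=(0, 0))
        passed, _, _ = mask_and_test(site([0.1, 0.5], [0.5, 0.9]), d, d=0.2)
        assert not passed

    @pytest.mark.parametrize("bad_d", [0.0, -0.1, 1.5])
    def test_invalid_d_rejected(self, bad_d):
        d = two_group_design(2, 2)
        with pytest.raises(NimblError):
            mask_and_test(site([0.1, 0.2], [0.5, 0.6]), d, d=bad_d)

    def test_one_sample_masked_per_iteration_irrespective_of_group(self):
        # both groups have an outlier; the globally most distant is masked first
        d = two_group_design(3, 3, m=(1, 1))
        passed, masked, _ = mask_and_test(
            site([0.10, 0.12, 0.90], [0.60, 0.62, 0.05]), d, d=0.3
        )
        assert passed
        # A's 0.90 (distance 0.78) goes before B's 0.05 (distance 0.55)
        assert masked == {"A": ["a2"], "B": ["b2"]}


# ---------------------------------------------------------------------------
# filter_sites
# ---------------------------------------------------------------------------

class TestFilterSites:
    def test_missing_beta_threshold(self, toy_dataset):
        out = filter_sites(toy_dataset, max_missing_samples=0)
        assert "cg03" not in out.site_ids  # has one missing beta
        assert "cg01" in out.site_ids

    def test_detection_p_threshold(self, toy_dataset):
        out = filter_sites(toy_dataset, p_cutoff=0.05, max_fail_samples=0,
                           max_missing_samples=1)
        assert "cg04" not in out.site_ids  # one failed detection
        assert "cg03" in out.site_ids

    def test_island_only_predicate(self, toy_dataset, toy_annotation):
        out = filter_sites(toy_dataset, max_missing_samples=4, max_fail_samples=4,
                           ann=toy_annotation, keep=islands_only)
        assert out.site_ids == ["cg01", "cg04"]

    def test_site_absent_from_annotation_removed_with_warning(self, toy_dataset, toy_annotation):
        sub = toy_annotation.subset(["cg01", "cg02", "cg03"])
        with pytest.warns(UserWarning, match="missing from annotation"):
            out = filter_sites(toy_dataset, max_missing_samples=4, max_fail_samples=4,
                               ann=sub, keep=lambda s: True)
        assert "cg04" not in out.site_ids

    def test_beta_only_input_skips_detection_filter(self, toy_dataset):
        ds = BetaDataset(
            toy_dataset.beta,
            nanlike(toy_dataset.detection_p),
        )
        with pytest.warns(UserWarning, match="no detection p-values"):
            out = filter_sites(ds, max_fail_samples=0, max_missing_samples=1)
        assert len(out.site_ids) == 4


# ---------------------------------------------------------------------------
# detect_dm
# ---------------------------------------------------------------------------

class TestDetectDM:
    def test_two_site_ranking_by_score(self):
        d = two_group_design(2, 2)
        beta = pd.DataFrame(
            {
                "a0": [0.10, 0.10],
                "a1": [0.10, 0.20],
                "b0": [0.60, 0.50],
                "b1": [0.60, 0.60],
            },
            index=["site1", "site2"],
        )
        ds = BetaDataset(beta, nanlike(beta))
        records = detect_dm(ds, d, d=0.1)
        assert [(r.rank, r.site_id) for r in records] == [(1, "site1"), (2, "site2")]
        assert records[0].score == pytest.approx(0.5)
        assert records[1].score == pytest.approx(0.2)

    def test_direction_labels(self):
        d = two_group_design(2, 2)
        beta = pd.DataFrame(
            {"a0": [0.1, 0.9], "a1": [0.1, 0.9], "b0": [0.6, 0.2], "b1": [0.6, 0.2]},
            index=["up", "down"],
        )
        ds = BetaDataset(beta, nanlike(beta))
        by_id = {r.site_id: r for r in detect_dm(ds, d, d=0.1)}
        assert by_id["up"].direction == "hyper_in_group2"
        assert by_id["down"].direction == "hypo_in_group2"

    def test_range_constraint_rejects_out_of_interval_group(self):
        # require group A hypomethylated (<= 0.3): site2 violates
        d = two_group_design(2, 2, ranges={"A": (0.0, 0.3)})
        beta = pd.DataFrame(
            {"a0": [0.1, 0.4], "a1": [0.2, 0.45], "b0": [0.6, 0.9], "b1": [0.7, 0.95]},
            index=["site1", "site2"],
        )
        ds = BetaDataset(beta, nanlike(beta))
        assert [r.site_id for r in detect_dm(ds, d, d=0.1)] == ["site1"]

    def test_range_constraint_applies_to_unmasked_only(self):
        d = two_group_design(3, 2, m=(1, 0), ranges={"A": (0.0, 0.3)})
        s = pd.DataFrame(
            {"a0": [0.10], "a1": [0.15], "a2": [0.80], "b0": [0.55], "b1": [0.60]},
            index=["s1"],
        )
        ds = BetaDataset(s, nanlike(s))
        records = detect_dm(ds, d, d=0.2)
        assert len(records) == 1
        assert records[0].masked == {"A": ["a2"], "B": []}

    def test_masking_flags_rescued_sites(self):
        d = two_group_design(3, 3, m=(1, 1))
        beta = pd.DataFrame(
            {
                "a0": [0.10, 0.10], "a1": [0.15, 0.15], "a2": [0.20, 0.65],
                "b0": [0.60, 0.60], "b1": [0.65, 0.65], "b2": [0.70, 0.70],
            },
            index=["clean", "rescued"],
        )
        ds = BetaDataset(beta, nanlike(beta))
        by_id = {r.site_id: r for r in detect_dm(ds, d, d=0.2)}
        assert not by_id["clean"].flagged
        assert by_id["rescued"].flagged and by_id["rescued"].n_masked == {"A": 1, "B": 0}

    def test_ranks_are_a_total_order(self):
        ds, _, design, _ = simulate(SimConfig(n_sites=500, seed=3))
        records = detect_dm(ds, design.with_mask_limits(1, 1), d=0.2)
        assert [r.rank for r in records] == list(range(1, len(records) + 1))

    def test_score_identity_holds_on_every_record(self):
        ds, _, design, _ = simulate(SimConfig(n_sites=500, seed=4))
        for r in detect_dm(ds, design.with_mask_limits(2, 2), d=0.1):
            assert r.score == pytest.approx(2 * r.beta_val_dist - r.median_diff, abs=1e-12)
            assert r.median_diff >= r.beta_val_dist - 1e-12


# ---------------------------------------------------------------------------
# Oracles and monotonicity
# ---------------------------------------------------------------------------

def brute_force_detected(values_a, values_b, d, m1, m2):
    """Independent oracle: enumerate every masking of <= m per group."""
    va = [v for v in values_a if not np.isnan(v)]
    vb = [v for v in values_b if not np.isnan(v)]
    for k1 in range(min(m1, len(va) - 1) + 1):
        for k2 in range(min(m2, len(vb) - 1) + 1):
            for drop_a in itertools.combinations(range(len(va)), k1):
                ra = [v for i, v in enumerate(va) if i not in drop_a]
                for drop_b in itertools.combinations(range(len(vb)), k2):
                    rb = [v for i, v in enumerate(vb) if i not in drop_b]
                    lo, hi = (ra, rb) if np.median(ra) <= np.median(rb) else (rb, ra)
                    if min(hi) - max(lo) >= d:
                        return True
    return False


class TestOracles:
    def test_m0_equals_minmax_oracle(self):
        """At m=0 detection must equal a one-line min/max gap test."""
        ds, _, design, _ = simulate(
            SimConfig(n_sites=2000, missing_rate=0.0, detection_fail_rate=0.0, seed=11)
        )
        detected = {r.site_id for r in detect_dm(ds, design, d=0.2)}
        a = ds.beta[design.samples_in("normal")].to_numpy()
        b = ds.beta[design.samples_in("tumor")].to_numpy()
        for i, sid in enumerate(ds.site_ids):
            lo, hi = (a[i], b[i]) if np.median(a[i]) <= np.median(b[i]) else (b[i], a[i])
            assert (hi.min() - lo.max() >= 0.2) == (sid in detected)

    def test_greedy_is_subset_of_exhaustive(self):
        """Every greedy detection is confirmed by brute-force enumeration."""
        rng = np.random.default_rng(5)
        design = two_group_design(5, 6, m=(2, 2))
        n = 300
        beta = pd.DataFrame(
            rng.uniform(0, 1, size=(n, 11)).round(3),
            index=[f"s{i}" for i in range(n)],
            columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(6)],
        )
        ds = BetaDataset(beta, nanlike(beta))
        detected = {r.site_id for r in detect_dm(ds, design, d=0.25)}
        for i, sid in enumerate(ds.site_ids):
            if sid in detected:
                assert brute_force_detected(beta.iloc[i, :5], beta.iloc[i, 5:], 0.25, 2, 2)

    def test_monotone_in_d(self):
        ds, _, design, _ = simulate(SimConfig(n_sites=2000, seed=12))
        design = design.with_mask_limits(1, 1)
        loose = {r.site_id for r in detect_dm(ds, design, d=0.1)}
        strict = {r.site_id for r in detect_dm(ds, design, d=0.2)}
        assert strict <= loose

    def test_monotone_in_m(self):
        ds, _, design, _ = simulate(
            SimConfig(n_sites=2000, contamination_per_group=(1, 1), seed=13)
        )
        sets = [
            {r.site_id for r in detect_dm(ds, design.with_mask_limits(m, m), d=0.15)}
            for m in (0, 1, 2)
        ]
        assert sets[0] <= sets[1] <= sets[2]


# ---------------------------------------------------------------------------
# gene_summary
# ---------------------------------------------------------------------------

class TestGeneSummary:
    def _fixture(self):
        # CHAD measured at 3 sites (TSS200 x2, Body x1); one site multi-gene
        rows = [
            ("cg1", "1", 100, [("CHAD", "TSS200")], "Island", "I", None),
            ("cg2", "1", 200, [("CHAD", "TSS200")], "Island", "I", None),
            ("cg3", "1", 300, [("CHAD", "Body"), ("OTH", "Body")], "OpenSea", "II", None),
            ("cg4", "2", 400, [("OTH", "5'UTR")], "OpenSea", "II", None),
        ]
        return make_annotation(rows)

    def _records(self, ids):
        from nimbl import DMRecord
        return [
            DMRecord(s, 0.3, 0.3, 0.3, {"A": [], "B": []}, "hyper_in_group2", i + 1)
            for i, s in enumerate(ids)
        ]

    def test_overall_is_union_not_sum(self):
        ann = self._fixture()
        summary = gene_summary(self._records(["cg1", "cg3"]), ann,
                               ["cg1", "cg2", "cg3", "cg4"])
        chad = summary.loc["CHAD"]
        assert chad["TSS200_measured"] == 2 and chad["TSS200_dm"] == 1
        assert chad["Body_measured"] == 1 and chad["Body_dm"] == 1
        assert chad["overall_measured"] == 3 and chad["overall_dm"] == 2

    def test_multi_gene_site_counts_once_per_gene(self):
        ann = self._fixture()
        summary = gene_summary(self._records(["cg3"]), ann, ["cg3", "cg4"])
        assert summary.loc["CHAD", "overall_dm"] == 1
        assert summary.loc["OTH", "overall_dm"] == 1

    def test_no_detections_still_lists_measured_counts(self):
        ann = self._fixture()
        summary = gene_summary([], ann, ["cg1", "cg2", "cg3", "cg4"])
        assert (summary["overall_dm"] == 0).all()
        assert summary.loc["CHAD", "overall_measured"] == 3


# ---------------------------------------------------------------------------
# Wilcoxon comparator
# ---------------------------------------------------------------------------

class TestWilcoxonComparator:
    def test_identical_group_distributions_yield_nothing(self):
        vals = [0.1, 0.3, 0.5, 0.7]
        beta = pd.DataFrame(
            {"a0": vals, "a1": vals, "a2": vals, "b0": vals, "b1": vals, "b2": vals},
            index=[f"s{i}" for i in range(4)],
        )
        ds = BetaDataset(beta, nanlike(beta))
        assert wilcoxon_comparator(ds, two_group_design(3, 3)) == []

    def test_single_site_bh_is_identity(self):
        beta = pd.DataFrame(
            {"a0": [0.1], "a1": [0.12], "a2": [0.11], "a3": [0.13],
             "b0": [0.9], "b1": [0.92], "b2": [0.91], "b3": [0.93]},
            index=["s0"],
        )
        ds = BetaDataset(beta, nanlike(beta))
        from scipy.stats import ranksums
        raw_p = ranksums(beta.iloc[0, :4], beta.iloc[0, 4:]).pvalue
        hits = wilcoxon_comparator(ds, two_group_design(4, 4), alpha=max(raw_p * 1.01, 1e-9))
        assert (hits == ["s0"]) == (raw_p < raw_p * 1.01)

    def test_constant_site_gets_p_one(self):
        beta = pd.DataFrame(
            {c: [0.5, 0.1 * (i + 1)] for i, c in
             enumerate(["a0", "a1", "b0", "b1"])},
            index=["const", "vary"],
        )
        ds = BetaDataset(beta, nanlike(beta))
        assert "const" not in wilcoxon_comparator(ds, two_group_design(2, 2), alpha=0.999)

    def test_recall_on_planted_shifts(self):
        """Planted delta=0.4 shifts among nulls are recovered with recall > 0.9."""
        ds, _, design, truth = simulate(
            SimConfig(n_sites=10_000, mixture=(0.3, 0.3, 0.3, 0.1), effect=0.4,
                      missing_rate=0.0, detection_fail_rate=0.0, seed=21)
        )
        hits = set(wilcoxon_comparator(ds, design, alpha=0.05))
        planted = truth.dm_sites
        recall = len(hits & planted) / len(planted)
        assert recall > 0.9
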