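import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nomvote import (
    CommunityProfile,
    OtuTable,
    classify_pair_interaction,
    classify_turnover,
    compute_poc,
    categorize_poc,
    filter_low_depth,
    group_by_dominance_frequency,
    label_status,
    occurrence_counts,
    pair_universe,
    partition_raw_vs_subs,
    poc_table,
    rank_top_n,
)
from conftest import profile_from


# -- depth filter ----------------------------------------------------


def test_filter_drops_samples_below_cut(small_table):
    filtered = filter_low_depth(small_table, 5000)
    # s1 has 5000 reads (kept: the cut is strict "fewer than"),
    # s2 has 5000, s3 has 4999 (removed)
    assert filtered.sample_ids == ["s1", "s2"]
    # OTU_3 only occurred in retained samples with zero counts -> dropped
    assert filtered.otu_ids == ["OTU_1", "OTU_2"]


def test_filter_zero_cut_is_identity(small_table):
    assert filter_low_depth(small_table, 0) == small_table.drop_empty_otus()


# -- dominant/rare labels --------------------------------------------


def test_label_status_threshold_is_inclusive():
    t = OtuTable(
        pd.DataFrame({"s": [2624, 2, 100, 7274]},
                     index=["OTU_1", "OTU_2", "OTU_3", "OTU_4"])
    )
    (p,) = label_status(t)
    assert p.status["OTU_1"] == "dominant"  # 26.24%
    assert p.status["OTU_2"] == "rare"  # 0.02%
    assert p.status["OTU_3"] == "dominant"  # exactly 1.00%
    assert abs(p.rel_abundance.sum() - 1.0) < 1e-12


def test_label_status_rejects_empty_sample():
    t = OtuTable(pd.DataFrame({"s": [0, 0]}, index=["a", "b"]))
    with pytest.raises(ValueError, match="filter"):
        label_status(t)


# -- partition and turnover ------------------------------------------


def test_partition_covers_all_observed_otus():
    raw = profile_from("RAW", {"OTU_1": 0.6, "OTU_2": 0.39, "OTU_3": 0.01})
    subs = [
        profile_from("s1", {"OTU_1": 0.9, "OTU_4": 0.1}),
        profile_from("s2", {"OTU_1": 0.5, "OTU_2": 0.5}),
    ]
    parts = partition_raw_vs_subs(raw, subs)
    assert parts.shared == {"OTU_1", "OTU_2"}
    assert parts.disappeared == {"OTU_3"}
    assert parts.appeared == {"OTU_4"}
    observed = raw.present_otus | subs[0].present_otus | subs[1].present_otus
    assert parts.universe == observed


def test_turnover_classes_and_sample_labels():
    raw = profile_from("RAW", {"OTU_1": 0.5, "OTU_2": 0.495, "OTU_3": 0.005})
    subs = [
        # OTU_1 raw-dominant stays dominant; appeared OTU_9 becomes dominant
        profile_from("s1", {"OTU_1": 0.6, "OTU_9": 0.35, "OTU_3": 0.05}),
        # R-to-D share exceeds D-to-D share
        profile_from("s2", {"OTU_3": 0.7, "OTU_1": 0.2, "OTU_2": 0.1}),
    ]
    tv = classify_turnover(raw, subs)
    occ = tv.occurrences.set_index(["otu_id", "sample_id"])["class"]
    assert occ[("OTU_1", "s1")] == "D-to-D"
    assert occ[("OTU_9", "s1")] == "R-to-D"  # appeared taxa count as raw-rare
    assert occ[("OTU_3", "s1")] == "R-to-D"
    assert occ[("OTU_1", "s2")] == "D-to-D"
    # shares per sample sum to the covered abundance
    covered = tv.sample_shares.sum(axis=1)
    assert covered["s1"] == pytest.approx(1.0)
    assert tv.sample_labels["s1"] == "D-to-D sub-community"
    assert tv.sample_labels["s2"] == "R-to-D sub-community"


def test_turnover_tie_labels_as_r_to_d():
    raw = profile_from("RAW", {"OTU_1": 0.995, "OTU_2": 0.005})
    subs = [profile_from("s1", {"OTU_1": 0.5, "OTU_2": 0.5})]
    tv = classify_turnover(raw, subs)
    assert tv.sample_labels["s1"] == "R-to-D sub-community"


def test_dominance_counts_sum_to_appearances():
    raw = profile_from("RAW", {"OTU_1": 0.99, "OTU_2": 0.01})
    subs = [
        profile_from(f"s{i}", {"OTU_1": 0.5 if i % 2 else 0.005,
                               "OTU_2": 0.5 if i % 2 else 0.995})
        for i in range(6)
    ]
    tv = classify_turnover(raw, subs)
    s = tv.otu_summary
    assert (s["dominant_count"] + s["rare_count"] == s["appearance_count"]).all()


@pytest.mark.parametrize(
    "dominant_in, expected",
    [(12, "A"), (10, "A"), (9, "B"), (1, "B"), (0, "C")],
)
def test_dominance_frequency_groups(dominant_in, expected):
    raw = profile_from("RAW", {"OTU_1": 1.0})
    subs = []
    for i in range(12):
        share = 0.5 if i < dominant_in else 0.001
        subs.append(
            profile_from(f"s{i}", {"OTU_2": share, "OTU_1": 1 - share})
        )
    tv = classify_turnover(raw, subs)
    groups = group_by_dominance_frequency(tv, universe=["OTU_1", "OTU_2", "OTU_3"])
    assert groups["OTU_2"] == expected
    assert groups["OTU_3"] == "D"  # never observed in any sub-community
    assert set(groups.unique()) <= {"A", "B", "C", "D"}


# -- POC -------------------------------------------------------------


@pytest.mark.parametrize(
    "occ_focal, co_occ, rounded, category",
    [
        (801, 125, 0.18, "exclusion preference"),
        (151, 125, 4.81, "coexistence preference"),
        (10, 10, math.inf, "complete coexistence"),
        (10, 0, 0.0, "complete exclusion"),
        (10, 5, 1.0, "neutral interaction"),
    ],
)
def test_compute_poc_examples(occ_focal, co_occ, rounded, category):
    poc = compute_poc(occ_focal, co_occ)
    assert poc.rounded == rounded
    assert poc.category == category


def test_compute_poc_rejects_impossible_counts():
    with pytest.raises(ValueError, match="impossible"):
        compute_poc(5, 6)
    with pytest.raises(ValueError):
        compute_poc(0, 0)


@settings(derandomize=True, max_examples=200)
@given(st.integers(1, 1000), st.integers(0, 1000))
def test_poc_invariants_hold_for_any_counts(occ_focal, co_occ):
    """Value/category invariants for every feasible occurrence tally."""
    co_occ = min(co_occ, occ_focal)
    poc = compute_poc(occ_focal, co_occ)
    assert (poc.value == 0) == (co_occ == 0)
    assert math.isinf(poc.value) == (co_occ == occ_focal)
    assert poc.category == categorize_poc(poc.value)
    if 0 < co_occ < occ_focal:
        assert poc.value == co_occ / (occ_focal - co_occ)
        # direction sign flips exactly at co-occurrence = half the occurrences
        assert (poc.value >= 1) == (2 * co_occ >= occ_focal)


def test_pair_universe_filter_is_strict():
    # OTU_A occurs in 11 samples, OTU_B in exactly 10 -> only A retained
    subs = []
    for i in range(11):
        shares = {"OTU_A": 0.6}
        if i < 10:
            shares["OTU_B"] = 0.4
        subs.append(profile_from(f"s{i}", shares))
    otus, pairs = pair_universe(subs, min_occurrence=10)
    assert otus == ["OTU_A"]
    assert pairs == 0


@pytest.mark.parametrize("n, expected", [(169, 28392), (2, 2), (1, 0)])
def test_ordered_pair_counts(n, expected):
    subs = [
        CommunityProfile.from_abundance(
            f"s{j}", pd.Series(1.0 / n, index=[f"OTU_{i}" for i in range(n)])
        )
        for j in range(11)
    ]
    otus, pairs = pair_universe(subs, min_occurrence=10)
    assert len(otus) == n
    assert pairs == expected


def test_pair_interaction_types():
    a = compute_poc(151, 125, "OTU_1", "OTU_13")  # 4.81
    b = compute_poc(801, 125, "OTU_13", "OTU_1")  # 0.18
    assert classify_pair_interaction(a, b).type == "positive+negative"
    assert classify_pair_interaction(b, a).type == "negative+positive"
    pp = classify_pair_interaction(compute_poc(3, 2), compute_poc(4, 3))
    assert pp.type == "positive+positive"
    nn = classify_pair_interaction(compute_poc(10, 3), compute_poc(10, 1))
    assert nn.type == "negative+negative"
    inf = classify_pair_interaction(compute_poc(5, 5), compute_poc(10, 5))
    assert inf.type == "positive+positive"  # +inf counts as positive


def test_poc_matches_brute_force_on_random_matrices(rng):
    """Tallied POC equals a per-sample recount, exactly, pair by pair."""
    for _ in range(20):
        pres = rng.random((20, 50)) < 0.3
        otus = [f"OTU_{i}" for i in range(20)]
        subs = [
            CommunityProfile.from_abundance(
                f"s{j}", pd.Series(pres[:, j] / max(1, pres[:, j].sum()), index=otus)
            )
            for j in range(50)
        ]
        table = poc_table(subs, min_occurrence=0)
        occ = occurrence_counts(subs)
        for row in table.itertuples():
            i, j = otus.index(row.focal), otus.index(row.other)
            x = int(pres[i].sum())
            co = int((pres[i] & pres[j]).sum())
            assert (row.occ_focal, row.co_occ) == (x, co)
            if co == x:
                assert math.isinf(row.value)
            else:
                assert row.value == co / (x - co)
            # single-pair API agrees with the vectorised table
            single = compute_poc(x, co, row.focal, row.other)
            assert single.value == row.value and single.category == row.category
        # a pair's type is positive+negative exactly when the directions disagree
        key = table.set_index(["focal", "other"])
        for i, a in enumerate(otus):
            for b in otus[i + 1 :]:
                pa = compute_poc(*key.loc[(a, b), ["occ_focal", "co_occ"]], a, b)
                pb = compute_poc(*key.loc[(b, a), ["occ_focal", "co_occ"]], b, a)
                pair = classify_pair_interaction(pa, pb)
                assert (pair.type == "positive+negative") == (
                    pa.value >= 1 > pb.value
                )


def test_poc_categories_partition_every_pair(rng):
    pres = rng.random((20, 50)) < 0.4
    otus = [f"OTU_{i}" for i in range(20)]
    subs = [
        CommunityProfile.from_abundance(
            f"s{j}", pd.Series(pres[:, j] / max(1, pres[:, j].sum()), index=otus)
        )
        for j in range(50)
    ]
    table = poc_table(subs, min_occurrence=0)
    freqs = table["category"].value_counts(normalize=True)
    assert freqs.sum() == pytest.approx(1.0)
    assert set(freqs.index) <= {
        "complete coexistence", "coexistence preference", "neutral interaction",
        "exclusion preference", "complete exclusion",
    }


# -- Top-N ranking ---------------------------------------------------


def test_rank_top_n_orders_and_breaks_ties_by_id():
    p1 = profile_from("s1", {"OTU_2": 0.7, "OTU_5": 0.2, "OTU_1": 0.1})
    p2 = profile_from("s2", {"OTU_3": 0.5, "OTU_2": 0.5})
    summary = rank_top_n([p1, p2], n=5)
    assert summary.top1["s1"] == "OTU_2"
    assert summary.top1["s2"] == "OTU_2"  # tie at 0.5 -> lexicographically smaller
    ranks_s1 = summary.ranks.query("sample_id == 's1'")
    assert ranks_s1["otu_id"].tolist() == ["OTU_2", "OTU_5", "OTU_1"]
    assert summary.top1_tally["OTU_2"] == 2


def test_rank_top_n_skips_empty_profiles():
    empty = CommunityProfile.from_abundance(
        "s0", pd.Series(0.0, index=["OTU_1"])
    )
    summary = rank_top_n([empty])
    assert "s0" not in summary.top1.index
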