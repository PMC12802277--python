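"""Occurrence analytics for dilution-cultivation sub-communities.

This module carries the empirical analysis stage: read-depth filtering,
dominant/rare labelling at the 1% relative-abundance cut, the
shared/disappeared/appeared partition between the raw community and its
cultivated sub-communities, status-turnover classes (D-to-D, R-to-D,
D-to-R, R-to-R), dominance-frequency groups A-D, Top-N ranking, and the
directed possibility-of-coexistence (POC) statistic

    POC(x -> y) = XYcoe / (X - XYcoe)

where ``X`` is the number of sub-communities in which the focal OTU x
occurs and ``XYcoe`` the number in which x and y co-occur.  POC = 0 is
complete exclusion, POC = +inf complete coexistence; values >= 1 mark a
positive effect of the focal OTU's presence on the partner's occurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .otu_table import OtuTable

__all__ = [
    "DOMINANCE_THRESHOLD",
    "CommunityProfile",
    "PartitionSets",
    "TurnoverResult",
    "PocValue",
    "PairInteraction",
    "DominanceSummary",
    "filter_low_depth",
    "label_status",
    "partition_raw_vs_subs",
    "classify_turnover",
    "group_by_dominance_frequency",
    "occurrence_counts",
    "compute_poc",
    "categorize_poc",
    "pair_universe",
    "poc_table",
    "classify_pair_interaction",
    "pair_interactions",
    "rank_top_n",
]

#: Relative-abundance cut separating dominant from rare taxa (inclusive).
DOMINANCE_THRESHOLD = 0.01

ABSENT = "absent"
RARE = "rare"
DOMINANT = "dominant"

TURNOVER_CLASSES = ("D-to-D", "R-to-D", "D-to-R", "R-to-R")

POC_COMPLETE_COEXISTENCE = "complete coexistence"
POC_COEXISTENCE_PREFERENCE = "coexistence preference"
POC_NEUTRAL = "neutral interaction"
POC_EXCLUSION_PREFERENCE = "exclusion preference"
POC_COMPLETE_EXCLUSION = "complete exclusion"
POC_CATEGORIES = (
    POC_COMPLETE_COEXISTENCE,
    POC_COEXISTENCE_PREFERENCE,
    POC_NEUTRAL,
    POC_EXCLUSION_PREFERENCE,
    POC_COMPLETE_EXCLUSION,
)


@dataclass
class CommunityProfile:
    """One sample's relative-abundance vector with dominant/rare labels.

    ``status`` is ``absent`` exactly where the abundance is zero and
    ``dominant`` where it is at or above the dominance threshold.
    """

    sample_id: str
    rel_abundance: pd.Series
    status: pd.Series

    @classmethod
    def from_counts(
        cls, sample_id: str, counts: pd.Series, threshold: float = DOMINANCE_THRESHOLD
    ) -> "CommunityProfile":
        total = float(counts.sum())
        if total <= 0:
            raise ValueError(
                f"sample {sample_id!r} has zero total reads; "
                "apply filter_low_depth before labelling"
            )
        rel = counts / total
        return cls.from_abundance(sample_id, rel, threshold)

    @classmethod
    def from_abundance(
        cls, sample_id: str, rel: pd.Series, threshold: float = DOMINANCE_THRESHOLD
    ) -> "CommunityProfile":
        rel = rel.astype(float)
        status = pd.Series(ABSENT, index=rel.index, dtype=object)
        status[rel > 0] = RARE
        status[rel >= threshold] = DOMINANT
        return cls(sample_id=sample_id, rel_abundance=rel, status=status)

    @property
    def present_otus(self) -> set[str]:
        return set(self.rel_abundance.index[self.rel_abundance > 0])

    @property
    def dominant_otus(self) -> set[str]:
        return set(self.status.index[self.status == DOMINANT])

    @property
    def rare_otus(self) -> set[str]:
        return set(self.status.index[self.status == RARE])


def filter_low_depth(table: OtuTable, min_reads: int = 5000) -> OtuTable:
    """Drop samples with fewer than ``min_reads`` total reads.

    The comparison is strict ("fewer than"): a sample with exactly
    ``min_reads`` reads is retained.  OTUs left with all-zero counts are
    dropped; sample and OTU order is otherwise preserved.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depths = table.sample_depths()
    keep = depths.index[depths >= min_reads]
    return table.select_samples(keep).drop_empty_otus()


def label_status(
    table: OtuTable, threshold: float = DOMINANCE_THRESHOLD
) -> list[CommunityProfile]:
    """Per-sample relative abundances with absent/rare/dominant labels."""
    rel = table.relative_abundance()
    profiles = []
    for sample in table.sample_ids:
        if table.counts[sample].sum() <= 0:
            raise ValueError(
                f"sample {sample!r} has zero total reads; "
                "apply filter_low_depth before labelling"
            )
        profiles.append(
            CommunityProfile.from_abundance(sample, rel[sample], threshold)
        )
    return profiles


@dataclass(frozen=True)
class PartitionSets:
    """Disjoint cover of all observed OTUs relative to the raw community."""

    shared: frozenset
    disappeared: frozenset
    appeared: frozenset

    @property
    def universe(self) -> frozenset:
        return self.shared | self.disappeared | self.appeared


def partition_raw_vs_subs(
    raw: CommunityProfile, subs: list[CommunityProfile]
) -> PartitionSets:
    """Split observed OTUs into shared / disappeared / appeared.

    shared: present in the raw community and in at least one sub-community;
    disappeared: present in raw only; appeared: present only in
    sub-communities (typically taxa below the raw detection limit that
    were retrieved by dilution-cultivation).
    """
    raw_set = raw.present_otus
    sub_set: set[str] = set()
    for p in subs:
        sub_set |= p.present_otus
    return PartitionSets(
        shared=frozenset(raw_set & sub_set),
        disappeared=frozenset(raw_set - sub_set),
        appeared=frozenset(sub_set - raw_set),
    )


@dataclass
class TurnoverResult:
    """Status turnover of every OTU occurrence from raw to sub-communities.

    ``occurrences`` is a long table with one row per (OTU, sample)
    presence, carrying the raw status (appeared OTUs count as raw-rare),
    the sub-community status and the turnover class.  ``otu_summary``
    aggregates appearance/dominant/rare counts per OTU; ``sample_shares``
    holds the per-sample abundance share of each turnover class, and
    ``sample_labels`` tags each sample as a D-to-D or R-to-D
    sub-community by comparing those two shares (ties go to R-to-D).
    """

    occurrences: pd.DataFrame
    otu_summary: pd.DataFrame
    sample_shares: pd.DataFrame
    sample_labels: pd.Series


def classify_turnover(
    raw: CommunityProfile, subs: list[CommunityProfile]
) -> TurnoverResult:
    raw_dominant = raw.dominant_otus
    rows = []
    for p in subs:
        for otu in sorted(p.present_otus):
            raw_status = DOMINANT if otu in raw_dominant else RARE
            sub_status = p.status[otu]
            klass = (
                f"{'D' if raw_status == DOMINANT else 'R'}-to-"
                f"{'D' if sub_status == DOMINANT else 'R'}"
            )
            rows.append(
                (otu, p.sample_id, raw_status, sub_status, klass,
                 float(p.rel_abundance[otu]))
            )
    occ = pd.DataFrame(
        rows,
        columns=["otu_id", "sample_id", "raw_status", "sub_status", "class",
                 "rel_abundance"],
    )
    if len(occ):
        summary = occ.groupby("otu_id").agg(
            raw_status=("raw_status", "first"),
            appearance_count=("sample_id", "count"),
            dominant_count=("sub_status", lambda s: int((s == DOMINANT).sum())),
            rare_count=("sub_status", lambda s: int((s == RARE).sum())),
        )
        shares = (
            occ.pivot_table(
                index="sample_id", columns="class", values="rel_abundance",
                aggfunc="sum", fill_value=0.0,
            )
            .reindex(columns=list(TURNOVER_CLASSES), fill_value=0.0)
        )
        shares.columns.name = None
    else:
        summary = pd.DataFrame(
            columns=["raw_status", "appearance_count", "dominant_count",
                     "rare_count"]
        )
        shares = pd.DataFrame(columns=list(TURNOVER_CLASSES))
    labels = pd.Series(
        np.where(shares["D-to-D"] > shares["R-to-D"],
                 "D-to-D sub-community", "R-to-D sub-community"),
        index=shares.index,
        dtype=object,
    )
    return TurnoverResult(
        occurrences=occ, otu_summary=summary, sample_shares=shares,
        sample_labels=labels,
    )


def group_by_dominance_frequency(
    turnover: TurnoverResult,
    universe=None,
    group_a_min: int = 10,
) -> pd.Series:
    """Assign each OTU a dominance-frequency group.

    A: dominant in >= ``group_a_min`` sub-communities; B: dominant in 1 to
    ``group_a_min``-1; C: present somewhere but never dominant; D: absent
    from every sub-community.  ``universe`` defaults to the OTUs observed
    in the sub-communities; pass the full observed set (raw plus subs) so
    that disappeared OTUs receive group D.
    """
    dom = turnover.otu_summary["dominant_count"] if len(turnover.otu_summary) else pd.Series(dtype=int)
    if universe is None:
        universe = list(turnover.otu_summary.index)
    groups = {}
    for otu in universe:
        d = int(dom.get(otu, -1))
        if d < 0:
            groups[otu] = "D"
        elif d >= group_a_min:
            groups[otu] = "A"
        elif d >= 1:
            groups[otu] = "B"
        else:
            groups[otu] = "C"
    return pd.Series(groups, dtype=object).sort_index()


# -- POC -------------------------------------------------------------


@dataclass(frozen=True)
class PocValue:
    """Directed co-occurrence statistic for an ordered OTU pair."""

    focal_otu: str
    other_otu: str
    occ_focal: int
    co_occ: int
    value: float
    category: str

    @property
    def rounded(self) -> float:
        """Display value at two decimals (finite values only)."""
        return self.value if math.isinf(self.value) else round(self.value, 2)


def categorize_poc(value: float) -> str:
    """Map a POC value to one of the five coexistence categories."""
    if value < 0:
        raise ValueError("POC value must be >= 0")
    if math.isinf(value):
        return POC_COMPLETE_COEXISTENCE
    if value == 0:
        return POC_COMPLETE_EXCLUSION
    if value == 1:
        return POC_NEUTRAL
    return POC_COEXISTENCE_PREFERENCE if value > 1 else POC_EXCLUSION_PREFERENCE


def compute_poc(
    occ_focal: int, co_occ: int, focal_otu: str = "", other_otu: str = ""
) -> PocValue:
    """POC of the ordered pair (focal -> other) from occurrence tallies.

    ``occ_focal`` is the number of sub-communities containing the focal
    OTU and ``co_occ`` the number containing both.  The value is
    ``co_occ / (occ_focal - co_occ)``, +inf when the focal OTU never
    occurs without the partner.
    """
    if occ_focal <= 0:
        raise ValueError("occ_focal must be positive")
    if co_occ < 0 or co_occ > occ_focal:
        raise ValueError(
            f"impossible counts: co_occ={co_occ} not in [0, occ_focal={occ_focal}]"
        )
    value = math.inf if co_occ == occ_focal else co_occ / (occ_focal - co_occ)
    return PocValue(
        focal_otu=focal_otu,
        other_otu=other_otu,
        occ_focal=int(occ_focal),
        co_occ=int(co_occ),
        value=value,
        category=categorize_poc(value),
    )


def occurrence_counts(subs: list[CommunityProfile]) -> pd.Series:
    """Number of sub-communities in which each OTU occurs."""
    if not subs:
        return pd.Series(dtype=int)
    return _presence_frame(subs).sum(axis=1).astype(int)


def _presence_frame(subs: list[CommunityProfile]) -> pd.DataFrame:
    idx = sorted(set().union(*(set(p.rel_abundance.index) for p in subs)))
    return pd.DataFrame(
        {p.sample_id: (p.rel_abundance > 0).reindex(idx, fill_value=False)
         for p in subs}
    )


def pair_universe(
    subs: list[CommunityProfile], min_occurrence: int = 10
) -> tuple[list[str], int]:
    """OTUs occurring in strictly more than ``min_occurrence`` samples.

    Returns the retained OTU IDs (sorted) and the number of ordered pairs
    n*(n-1) they generate.
    """
    occ = occurrence_counts(subs)
    otus = sorted(occ.index[occ > min_occurrence])
    n = len(otus)
    return otus, n * (n - 1)


def poc_table(
    subs: list[CommunityProfile], min_occurrence: int = 10
) -> pd.DataFrame:
    """Long-format POC for every ordered pair in the filtered universe.

    Columns: focal, other, occ_focal, co_occ, value, category.  The value
    column is full precision; round for display.
    """
    otus, _ = pair_universe(subs, min_occurrence)
    pres = _presence_frame(subs).reindex(otus, fill_value=False).to_numpy(dtype=np.int64)
    co = pres @ pres.T
    occ = np.diag(co).copy()
    rows = []
    for i, focal in enumerate(otus):
        for j, other in enumerate(otus):
            if i == j:
                continue
            c = int(co[i, j])
            x = int(occ[i])
            value = math.inf if c == x else c / (x - c)
            rows.append((focal, other, x, c, value, categorize_poc(value)))
    return pd.DataFrame(
        rows, columns=["focal", "other", "occ_focal", "co_occ", "value", "category"]
    )


@dataclass(frozen=True)
class PairInteraction:
    """Interaction type of an unordered pair from its two directed POCs."""

    otu_a: str
    otu_b: str
    poc_ab: PocValue
    poc_ba: PocValue
    type: str


def _sign(value: float) -> str:
    return "positive" if value >= 1 else "negative"


def classify_pair_interaction(poc_ab: PocValue, poc_ba: PocValue) -> PairInteraction:
    """Combine both directions into one of the four interaction types.

    A direction is positive when its POC is >= 1 (+inf included), negative
    when it lies in [0, 1).
    """
    return PairInteraction(
        otu_a=poc_ab.focal_otu,
        otu_b=poc_ba.focal_otu,
        poc_ab=poc_ab,
        poc_ba=poc_ba,
        type=f"{_sign(poc_ab.value)}+{_sign(poc_ba.value)}",
    )


def pair_interactions(
    subs: list[CommunityProfile], min_occurrence: int = 10
) -> pd.DataFrame:
    """Interaction types for every unordered pair in the filtered universe."""
    poc = poc_table(subs, min_occurrence)
    key = poc.set_index(["focal", "other"])["value"]
    rows = []
    otus = sorted(set(poc["focal"]))
    for i, a in enumerate(otus):
        for b in otus[i + 1 :]:
            vab, vba = key[(a, b)], key[(b, a)]
            rows.append((a, b, vab, vba, f"{_sign(vab)}+{_sign(vba)}"))
    return pd.DataFrame(rows, columns=["otu_a", "otu_b", "poc_ab", "poc_ba", "type"])


# -- dominance ranking -----------------------------------------------


@dataclass
class DominanceSummary:
    """Top-N abundance ranking per sample plus aggregate Top1 tallies."""

    ranks: pd.DataFrame  # sample_id, rank, otu_id, share
    top1: pd.Series  # sample_id -> otu_id
    top1_tally: pd.Series  # otu_id -> number of samples topped


def rank_top_n(profiles: list[CommunityProfile], n: int = 5) -> DominanceSummary:
    """Rank each sample's OTUs by share, descending, ties by OTU ID."""
    rows = []
    top1 = {}
    for p in profiles:
        present = p.rel_abundance[p.rel_abundance > 0]
        if present.empty:
            continue
        order = sorted(present.items(), key=lambda kv: (-kv[1], kv[0]))
        for rank, (otu, share) in enumerate(order[:n], start=1):
            rows.append((p.sample_id, rank, otu, float(share)))
        top1[p.sample_id] = order[0][0]
    ranks = pd.DataFrame(rows, columns=["sample_id", "rank", "otu_id", "share"])
    top1_s = pd.Series(top1, dtype=object)
    tally = top1_s.value_counts().sort_index() if len(top1_s) else pd.Series(dtype=int)
    return DominanceSummary(ranks=ranks, top1=top1_s, top1_tally=tally)
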