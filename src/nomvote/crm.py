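"""Consumer-resource simulations of dominant-taxon emergence.

The model couples species biomass N_i to shared resource concentrations
R_j through

    dN_i/dt = N_i (g_i sum_j U_ij R_j - m)
    dR_j/dt = -R_j sum_i g_i N_i U_ij

with growth rate g_i, uptake matrix U, and a uniform per-capita
maintenance cost m.  Species fall into four functional groups crossing
high/low growth rate with high/low metabolic flexibility (resource-use
breadth): HH, HL, LH, LL.

Three simulation campaigns probe the nomination-voting picture of
community assembly:

* ``run_nomination`` -- 80 species (20 per group) compete under 1, 5, 10
  or 20 resources; species with fast growth and broad resource use (HH)
  are "nominated" as candidate dominants, increasingly so as resource
  richness rises.
* ``run_voting`` -- 20 trait-equalised HH candidates (95% of the
  inoculum) assemble with 60 random rare background species (5%); the
  identity of the most abundant species (Top1) varies with the rare
  draw: the rare biosphere "votes".
* ``run_structured`` -- the rare background is biased to overlap the
  resource profiles of the currently successful candidates; dominance
  shifts toward candidates whose profiles escape the interference.

Two deliberate asymmetries between the campaigns reflect the biology:
in nomination the uptake matrix is populated freely, so breadth is a raw
advantage (dominant-prone taxa carry more metabolic genes); in the
voting campaigns all species are normalised to a common uptake budget
(a metabolic trade-off), which equalises candidates and gives rare
specialists enough per-resource uptake to matter despite their 5% share.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "GROUPS",
    "SpeciesTraits",
    "SimulationConfig",
    "TrajectoryResult",
    "ExperimentSummary",
    "StructuredResult",
    "sample_traits",
    "make_candidates",
    "rhs",
    "simulate",
    "run_nomination",
    "run_voting",
    "run_structured",
    "total_variation",
]

GROUPS = ("HH", "HL", "LH", "LL")

#: Disjoint trait strata: growth rate (per time) and resource-use breadth
#: (fraction of available resources, floored at one resource).
GROWTH_STRATA = {"H": (0.8, 1.2), "L": (0.2, 0.4)}
BREADTH_STRATA = {"H": (0.6, 0.9), "L": (0.1, 0.3)}
UPTAKE_RANGE = (0.5, 1.5)

#: Total inoculum biomass relative to a resource pool of 10 units --
#: a dilute inoculum in rich medium, which lengthens the growth phase
#: enough for rare-taxon interference to act.
DEFAULT_INOCULUM = 1e-6


@dataclass
class SpeciesTraits:
    """Growth rate, usable-resource set and uptake row for one species."""

    species_id: str
    group: str
    growth_rate: float
    usable_resources: tuple
    uptake: np.ndarray

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if len(self.usable_resources) == 0:
            raise ValueError("usable_resources must be nonempty")
        off = np.ones(len(self.uptake), dtype=bool)
        off[list(self.usable_resources)] = False
        if (self.uptake[off] != 0).any():
            raise ValueError("uptake must be zero outside usable_resources")
        if (self.uptake < 0).any():
            raise ValueError("uptake must be non-negative")


def sample_traits(
    group: str,
    n_resources: int,
    rng: np.random.Generator,
    species_id: str = "",
    growth_rate: float | None = None,
    breadth_fraction: float | None = None,
    budget: float | None = None,
    resource_weights: np.ndarray | None = None,
) -> SpeciesTraits:
    """Draw one species from its group's trait strata.

    Growth rate and breadth come from the group's (disjoint) high/low
    ranges unless pinned explicitly.  ``resource_weights`` biases both
    which resources are usable and how the uptake is distributed across
    them; ``budget`` rescales the uptake row to a fixed total (the
    metabolic trade-off used in the voting campaigns).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if n_resources < 1:
        raise ValueError("n_resources must be >= 1")
    g = growth_rate if growth_rate is not None else rng.uniform(*GROWTH_STRATA[group[0]])
    bf = (
        breadth_fraction
        if breadth_fraction is not None
        else rng.uniform(*BREADTH_STRATA[group[1]])
    )
    k = max(1, int(round(bf * n_resources)))
    p = None
    if resource_weights is not None:
        p = np.asarray(resource_weights, dtype=float)
        p = p / p.sum()
    res = np.sort(rng.choice(n_resources, size=k, replace=False, p=p))
    uptake = np.zeros(n_resources)
    uptake[res] = rng.uniform(*UPTAKE_RANGE, size=k)
    if resource_weights is not None:
        uptake[res] *= p[res] + 1e-12
    if budget is not None:
        uptake *= budget / uptake.sum()
    return SpeciesTraits(
        species_id=species_id,
        group=group,
        growth_rate=float(g),
        usable_resources=tuple(int(r) for r in res),
        uptake=uptake,
    )


def make_candidates(
    rng: np.random.Generator,
    n_candidates: int = 20,
    n_resources: int = 10,
    budget: float = 1.0,
) -> list[SpeciesTraits]:
    """Trait-equalised HH candidates for the voting campaigns.

    Every candidate has the HH-stratum midpoint growth rate, 70% breadth
    and a common uptake budget; they differ only in which resources they
    use and how the budget is spread over them, so intrinsic
    competitiveness is uniform and the rare background decides.
    """
    return [
        sample_traits(
            "HH",
            n_resources,
            rng,
            species_id=f"HH_{i + 1:02d}",
            growth_rate=1.0,
            breadth_fraction=0.7,
            budget=budget,
        )
        for i in range(n_candidates)
    ]


@dataclass
class SimulationConfig:
    """Numerical and environmental settings for one community run.

    The resource pool totals ``total_resource`` split equally across
    resources (comparable across richness levels); ``inoculum_scale`` is
    the summed initial biomass when none is given explicitly.  Species
    ending below ``extinction_floor`` x (initial total biomass) are
    reported extinct.
    """

    n_resources: int = 10
    total_resource: float = 10.0
    initial_resource: np.ndarray | None = None
    maintenance: float = 0.1
    t_end: float = 100.0
    inoculum_scale: float = DEFAULT_INOCULUM
    extinction_floor: float = 1e-9
    rtol: float = 1e-8
    atol: float = 1e-10

    def validate(self) -> None:
        if self.n_resources < 1:
            raise ValueError("n_resources must be >= 1")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.maintenance < 0:
            raise ValueError("maintenance must be >= 0")
        if self.initial_resource is not None and (
            np.asarray(self.initial_resource) < 0
        ).any():
            raise ValueError("initial_resource must be non-negative")


def _pack(traits):
    """Accept a list of SpeciesTraits or a (g, U) pair."""
    if isinstance(traits, tuple) and len(traits) == 2:
        g, U = traits
        return np.asarray(g, float), np.asarray(U, float), None
    g = np.array([t.growth_rate for t in traits])
    U = np.vstack([t.uptake for t in traits])
    ids = [t.species_id or f"sp_{i + 1}" for i, t in enumerate(traits)]
    return g, U, ids


def rhs(N, R, traits, m: float):
    """Time derivatives (dN, dR) of the consumer-resource equations."""
    g, U, _ = _pack(traits)
    N = np.asarray(N, float)
    R = np.asarray(R, float)
    if N.shape[0] != g.shape[0] or R.shape[0] != U.shape[1]:
        raise ValueError(
            f"dimension mismatch: {N.shape[0]} species vs {g.shape[0]} trait rows, "
            f"{R.shape[0]} resources vs {U.shape[1]} uptake columns"
        )
    dN = N * (g * (U @ R) - m)
    dR = -R * ((g * N) @ U)
    return dN, dR


@dataclass
class TrajectoryResult:
    """Final state of one community run."""

    species_ids: list[str]
    groups: list[str]
    final_biomass: pd.Series
    final_resources: np.ndarray
    relative_abundance: pd.Series
    group_shares: pd.Series
    top1: str | None
    survivors: list[str]


def simulate(
    traits,
    config: SimulationConfig | None = None,
    initial_biomass: np.ndarray | None = None,
) -> TrajectoryResult:
    """Integrate one community to ``t_end`` and summarise the outcome.

    Species at or below the extinction floor at ``t_end`` are reported
    extinct and excluded from the relative abundances; round-off
    negatives are clamped to zero.
    """
    config = config or SimulationConfig()
    config.validate()
    g, U, ids = _pack(traits)
    groups = [t.group for t in traits] if ids is not None else ["?"] * len(g)
    if ids is None:
        ids = [f"sp_{i + 1}" for i in range(len(g))]
    n, n_res = U.shape
    if initial_biomass is None:
        N0 = np.full(n, config.inoculum_scale / n)
    else:
        N0 = np.asarray(initial_biomass, float)
        if N0.shape[0] != n:
            raise ValueError("initial_biomass length must match species count")
    if config.initial_resource is None:
        R0 = np.full(n_res, config.total_resource / n_res)
    else:
        R0 = np.asarray(config.initial_resource, float)
        if R0.shape[0] != n_res:
            raise ValueError("initial_resource length must match n_resources")
    m = config.maintenance

    def fun(t, y):
        N = np.maximum(y[:n], 0.0)
        R = np.maximum(y[n:], 0.0)
        dN = N * (g * (U @ R) - m)
        dR = -R * ((g * N) @ U)
        return np.concatenate([dN, dR])

    sol = solve_ivp(
        fun,
        (0.0, config.t_end),
        np.concatenate([N0, R0]),
        method="LSODA",
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed after t={sol.t[-1]:.3g}: {sol.message}"
        )
    y = np.maximum(sol.y[:, -1], 0.0)
    N, R = y[:n].copy(), y[n:]
    floor = config.extinction_floor * N0.sum()
    N[N < floor] = 0.0
    total = N.sum()
    rel = N / total if total > 0 else np.zeros(n)
    shares = pd.Series(0.0, index=list(GROUPS))
    for grp, r in zip(groups, rel):
        if grp in shares.index:
            shares[grp] += r
    top1 = ids[int(np.argmax(N))] if total > 0 else None
    return TrajectoryResult(
        species_ids=ids,
        groups=groups,
        final_biomass=pd.Series(N, index=ids),
        final_resources=R,
        relative_abundance=pd.Series(rel, index=ids),
        group_shares=shares,
        top1=top1,
        survivors=[i for i, v in zip(ids, N) if v > 0],
    )


@dataclass
class ExperimentSummary:
    """Aggregated outcome of a simulation campaign."""

    campaign: str
    scenario: str
    n_replicates: int
    replicates: list  # per-replicate digests (dicts)
    group_shares: pd.DataFrame | None = None  # per (level, replicate)
    mean_group_shares: pd.DataFrame | None = None  # level x group
    top1_counts: pd.Series | None = None  # species_id -> tally


def _spawn_rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *path]))


def run_nomination(
    replicates: int = 100,
    resource_levels=(1, 5, 10, 20),
    n_per_group: int = 20,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> ExperimentSummary:
    """Step 1: trait-based nomination across resource richness levels.

    Per level and replicate, 20 fresh species per functional group (80
    in total, equal initial biomass) compete; group shares of the final
    community are aggregated into per-level means.
    """
    base = config or SimulationConfig()
    rows = {}
    digests = []
    for level in resource_levels:
        cfg = replace(base, n_resources=int(level), initial_resource=None)
        for rep in range(replicates):
            rng = _spawn_rng(seed, int(level), rep)
            traits = [
                sample_traits(
                    grp, cfg.n_resources, rng, species_id=f"{grp}_{i + 1:02d}"
                )
                for grp in GROUPS
                for i in range(n_per_group)
            ]
            result = simulate(traits, cfg)
            rows[(level, rep)] = result.group_shares
            digests.append(
                {"resource_level": level, "replicate": rep, "top1": result.top1,
                 "group_shares": result.group_shares.to_dict()}
            )
    shares = pd.DataFrame(rows).T
    shares.index.names = ["resource_level", "replicate"]
    means = shares.groupby(level="resource_level").mean()
    return ExperimentSummary(
        campaign="nomination",
        scenario="trait_strata",
        n_replicates=replicates,
        replicates=digests,
        group_shares=shares,
        mean_group_shares=means,
    )


def _rare_background(
    rng: np.random.Generator,
    n_rare: int,
    n_resources: int,
    even_split: bool,
    resource_weights: np.ndarray | None,
    budget: float,
) -> list[SpeciesTraits]:
    rare_groups = ("HL", "LH", "LL")
    if even_split:
        groups = [rare_groups[i % 3] for i in range(n_rare)]
    else:
        groups = [rare_groups[i] for i in rng.integers(0, 3, size=n_rare)]
    return [
        sample_traits(
            grp,
            n_resources,
            rng,
            species_id=f"bg_{i + 1:02d}",
            resource_weights=resource_weights,
            budget=budget,
        )
        for i, grp in enumerate(groups)
    ]


def _voting_campaign(
    candidates: list[SpeciesTraits],
    replicates: int,
    config: SimulationConfig,
    seed: int,
    n_rare: int,
    even_split: bool,
    resource_weights: np.ndarray | None,
    scenario: str,
) -> ExperimentSummary:
    n_cand = len(candidates)
    tallies: dict[str, int] = {}
    digests = []
    for rep in range(replicates):
        rng = _spawn_rng(seed, 1, rep)  # stream shared by paired scenarios
        rares = _rare_background(
            rng, n_rare, config.n_resources, even_split, resource_weights, budget=1.0
        )
        traits = candidates + rares
        n0 = np.concatenate(
            [
                np.full(n_cand, 0.95 * config.inoculum_scale / n_cand),
                np.full(n_rare, 0.05 * config.inoculum_scale / n_rare),
            ]
        )
        result = simulate(traits, config, initial_biomass=n0)
        winner = result.top1 if result.top1 is not None else "<none>"
        tallies[winner] = tallies.get(winner, 0) + 1
        digests.append(
            {"replicate": rep, "top1": winner,
             "candidate_share": float(result.relative_abundance.iloc[:n_cand].sum())}
        )
    counts = pd.Series(tallies, dtype=int).sort_index()
    return ExperimentSummary(
        campaign="voting",
        scenario=scenario,
        n_replicates=replicates,
        replicates=digests,
        top1_counts=counts,
    )


def run_voting(
    replicates: int = 100,
    n_candidates: int = 20,
    n_rare: int = 60,
    config: SimulationConfig | None = None,
    seed: int = 0,
    even_split: bool = False,
) -> ExperimentSummary:
    """Step 2: fixed HH candidates vs random rare backgrounds.

    One trait-equalised candidate pool (95% of the inoculum, sampled once
    from a dedicated stream and reused across replicates) assembles with
    60 fresh rare background species (5%) per replicate; the Top1 winner
    is tallied per replicate.
    """
    cfg = config or SimulationConfig()
    cand_rng = _spawn_rng(seed, 0)
    candidates = make_candidates(cand_rng, n_candidates, cfg.n_resources)
    return _voting_campaign(
        candidates, replicates, cfg, seed, n_rare, even_split, None, "random_rare"
    )


@dataclass
class StructuredResult:
    """Paired random vs structured voting campaigns."""

    random: ExperimentSummary
    structured: ExperimentSummary
    targeted: list[str]
    shielded: list[str]
    interference_weights: np.ndarray

    @property
    def tv_distance(self) -> float:
        return total_variation(
            self.random.top1_counts, self.structured.top1_counts
        )

    def wins(self, which: str = "structured") -> tuple[int, int]:
        """(targeted, shielded) aggregate Top1 wins in a scenario."""
        counts = (self.structured if which == "structured" else self.random).top1_counts
        t = int(sum(counts.get(c, 0) for c in self.targeted))
        s = int(sum(counts.get(c, 0) for c in self.shielded))
        return t, s


def total_variation(counts_a: pd.Series, counts_b: pd.Series) -> float:
    """Total-variation distance between two Top1 frequency vectors."""
    pa = counts_a / counts_a.sum()
    pb = counts_b / counts_b.sum()
    idx = pa.index.union(pb.index)
    return float(
        0.5 * (pa.reindex(idx, fill_value=0) - pb.reindex(idx, fill_value=0)).abs().sum()
    )


def run_structured(
    replicates: int = 100,
    targeted: int = 10,
    n_candidates: int = 20,
    n_rare: int = 60,
    config: SimulationConfig | None = None,
    seed: int = 0,
    even_split: bool = False,
    kappa: float = 6.0,
    structured_mix: float = 0.9,
) -> StructuredResult:
    """Step 3: structured rare taxa with biased resource overlap.

    The random-background campaign is run first and its Top1 frequencies
    define per-resource interference weights: resources the successful
    candidates draw on most get weight (frequency-weighted candidate
    uptake raised to ``kappa``, mixed ``structured_mix``/uniform).  The
    structured campaign then draws each rare species' usable resources
    with those weights and concentrates its uptake budget on them.  The
    ``targeted`` candidates most exposed to the interference weights
    (largest U . w -- by construction the incumbent winners) are compared
    with the remaining, shielded candidates.  ``targeted=0`` disables the
    bias and degenerates to a second random campaign.
    """
    cfg = config or SimulationConfig()
    if targeted > n_candidates:
        raise ValueError("targeted cannot exceed the candidate count")
    cand_rng = _spawn_rng(seed, 0)
    candidates = make_candidates(cand_rng, n_candidates, cfg.n_resources)
    random_summary = _voting_campaign(
        candidates, replicates, cfg, seed, n_rare, even_split, None, "random_rare"
    )

    cand_ids = [c.species_id for c in candidates]
    U = np.vstack([c.uptake for c in candidates])
    freq = np.array(
        [random_summary.top1_counts.get(cid, 0) for cid in cand_ids], dtype=float
    )
    if targeted == 0 or freq.sum() == 0:
        weights = None
        targeted_ids: list[str] = []
        shielded_ids = list(cand_ids)
        w_out = np.full(cfg.n_resources, 1.0 / cfg.n_resources)
    else:
        freq = freq / freq.sum()
        F = freq @ U
        w = (F / F.max()) ** kappa
        w = structured_mix * w / w.sum() + (1 - structured_mix) / cfg.n_resources
        exposure = U @ w
        order = np.argsort(-(exposure - np.arange(n_candidates) * 1e-12))
        targeted_ids = [cand_ids[i] for i in sorted(order[:targeted])]
        shielded_ids = [c for c in cand_ids if c not in targeted_ids]
        weights = w
        w_out = w
    structured_summary = _voting_campaign(
        candidates, replicates, cfg, seed, n_rare, even_split, weights,
        "structured_rare",
    )
    return StructuredResult(
        random=random_summary,
        structured=structured_summary,
        targeted=targeted_ids,
        shielded=shielded_ids,
        interference_weights=w_out,
    )
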