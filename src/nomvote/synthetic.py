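"""Synthetic dilution-cultivation communities.

Emulates the statistical structure of a dilution-to-extinction culturing
study: a soil-like raw community with a few dominant taxa over a
heavy-tailed rare biosphere, Poisson inoculation of 96-well plates at
several dilution factors, competitive sorting during cultivation, and
per-well amplicon sequencing with variable depth.  Every stage is driven
by a single seed and is reproducible end to end.

The default parameterisation mirrors the community the analysis stage
expects: 674 taxa of which the 16 dominants (>1% each) jointly hold
68.59% of the abundance, three dilution factors (1.0e-4, 0.5e-4, 1.0e-5)
filling 288 + 384 + 384 = 1,056 wells, and a sequencing-depth
distribution whose lower tail exercises the 5,000-read retention filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .occurrence import DOMINANCE_THRESHOLD, CommunityProfile
from .otu_table import OtuTable

__all__ = [
    "RawCommunitySpec",
    "RawCommunity",
    "DilutionSpec",
    "CultivationSpec",
    "Well",
    "generate_raw_community",
    "sample_inocula",
    "cultivate_and_sequence",
    "generate_campaign",
]


@dataclass
class RawCommunitySpec:
    """Parameters of the raw-community abundance distribution.

    ``abundance_shape`` is the log-normal sigma of the underlying rank
    abundances; larger values give a steeper head and a longer tail.
    Taxa whose relative abundance falls below ``detection_floor`` are
    flagged undetected: they exist in the community (and can seed wells)
    but are invisible to raw-community sequencing, which is what later
    lets OTUs "appear" in sub-communities.
    """

    n_otus: int = 674
    n_dominant: int = 16
    dominant_total_share: float = 0.6859
    abundance_shape: float = 1.5
    detection_floor: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.n_otus <= 0:
            raise ValueError("n_otus must be positive")
        if not 0 < self.n_dominant < self.n_otus:
            raise ValueError("need 0 < n_dominant < n_otus")
        if not 0 < self.dominant_total_share < 1:
            raise ValueError("dominant_total_share must lie in (0, 1)")
        if self.n_dominant * DOMINANCE_THRESHOLD >= self.dominant_total_share:
            raise ValueError(
                f"{self.n_dominant} dominants cannot each exceed "
                f"{DOMINANCE_THRESHOLD:.0%} within a total share of "
                f"{self.dominant_total_share:.2%}"
            )
        if self.abundance_shape <= 0:
            raise ValueError("abundance_shape must be positive")


@dataclass
class RawCommunity:
    """A raw community: true abundances plus sequencing detectability."""

    otu_ids: list[str]
    abundance: pd.Series  # true relative abundances, sums to 1
    undetected: pd.Series  # True where below the detection floor

    def observed_profile(self, sample_id: str = "RAW") -> CommunityProfile:
        """The community as raw sequencing sees it: undetected taxa absent."""
        rel = self.abundance.where(~self.undetected, 0.0)
        rel = rel / rel.sum()
        return CommunityProfile.from_abundance(sample_id, rel)

    def true_profile(self, sample_id: str = "RAW_TRUE") -> CommunityProfile:
        return CommunityProfile.from_abundance(sample_id, self.abundance)


def _cap_tail(tail: np.ndarray, total: float, cap: float) -> np.ndarray:
    """Scale ``tail`` to sum ``total`` with every entry < ``cap``.

    Water-filling: entries at the cap are frozen and the remainder is
    rescaled; terminates because the capped set only grows.
    """
    tail = tail * (total / tail.sum())
    capped = np.zeros(len(tail), dtype=bool)
    for _ in range(len(tail)):
        over = (tail > cap) & ~capped
        if not over.any():
            break
        tail[over] = cap
        capped |= over
        free = ~capped
        remaining = total - cap * capped.sum()
        if not free.any() or remaining <= 0:
            break
        tail[free] *= remaining / tail[free].sum()
    return tail


def generate_raw_community(spec: RawCommunitySpec) -> RawCommunity:
    """Draw a raw community profile with the requested dominance structure.

    Log-normal rank abundances are split at rank ``n_dominant``; the head
    is rescaled to sum to ``dominant_total_share`` (lifting any member
    below the 1% threshold toward the head mean if needed) and the tail
    to the complement, capped just below the threshold so that exactly
    ``n_dominant`` taxa are dominant whenever the tail has room to stay
    below 1% (always true at realistic richness).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k, n = spec.n_dominant, spec.n_otus
    thr = DOMINANCE_THRESHOLD
    x = np.sort(rng.lognormal(0.0, spec.abundance_shape, n))[::-1]

    head = x[:k] * (spec.dominant_total_share / x[:k].sum())
    floor = thr * 1.05
    if head.min() < floor:
        # blend toward the uniform head share until the smallest clears 1%
        mean = spec.dominant_total_share / k
        lam = (mean - floor) / (mean - head.min())
        head = lam * head + (1 - lam) * mean

    tail_total = 1.0 - spec.dominant_total_share
    tail = x[k:]
    cap = thr * 0.99
    if (n - k) * cap >= tail_total:
        tail = _cap_tail(tail, tail_total, cap)
    else:
        # too few tail taxa to keep each below 1%; leave the heavy tail
        tail = tail * (tail_total / tail.sum())

    abundance = np.concatenate([head, tail])
    abundance = abundance / abundance.sum()
    otu_ids = [f"OTU_{i + 1}" for i in range(n)]
    ab = pd.Series(abundance, index=otu_ids)
    return RawCommunity(
        otu_ids=otu_ids,
        abundance=ab,
        undetected=ab < spec.detection_floor,
    )


@dataclass
class DilutionSpec:
    """Dilution factors, plate layout and expected cells per well.

    Defaults follow a three-level dilution-to-extinction design: factors
    1.0e-4 (3 plates), 0.5e-4 (4 plates) and 1.0e-5 (4 plates) of
    96-well plates, 1,056 wells in total, with the expected inoculum
    (cells per well) proportional to the factor.
    """

    dilution_factors: tuple = (1.0e-4, 0.5e-4, 1.0e-5)
    wells_per_factor: tuple = (288, 384, 384)
    inoculum_cells: tuple = (200.0, 100.0, 20.0)
    seed: int = 0

    def validate(self) -> None:
        if not (
            len(self.dilution_factors)
            == len(self.wells_per_factor)
            == len(self.inoculum_cells)
        ):
            raise ValueError("dilution spec lists must have equal length")
        if any(f <= 0 for f in self.dilution_factors):
            raise ValueError("dilution factors must be positive")
        if any(c <= 0 for c in self.inoculum_cells):
            raise ValueError("inoculum_cells must be positive")
        if any(w <= 0 for w in self.wells_per_factor):
            raise ValueError("wells_per_factor must be positive")

    @property
    def total_wells(self) -> int:
        return int(sum(self.wells_per_factor))


@dataclass
class Well:
    """One inoculated well: integer founder cells per taxon."""

    well_id: str
    factor_index: int
    cells: np.ndarray


def _well_ids(wells_per_factor) -> list[tuple[str, int]]:
    ids = []
    plate = 0
    for fi, n_wells in enumerate(wells_per_factor):
        for w in range(int(n_wells)):
            if w % 96 == 0:
                plate += 1
            row = "ABCDEFGH"[(w % 96) // 12]
            col = (w % 96) % 12 + 1
            ids.append((f"P{plate:02d}_{row}{col}", fi))
    return ids


def sample_inocula(raw: RawCommunity, dil: DilutionSpec) -> list[Well]:
    """Poisson inoculation: founder cells per taxon per well.

    Each taxon's cell count is an independent Poisson draw with mean
    ``inoculum_cells x true relative abundance``, the standard
    dilution-to-extinction model in which occurrence in a well depends on
    initial abundance.  Undetected taxa participate: that is how taxa
    invisible to raw sequencing later appear in sub-communities.
    """
    dil.validate()
    rng = np.random.default_rng(dil.seed)
    ab = raw.abundance.to_numpy()
    wells = []
    for well_id, fi in _well_ids(dil.wells_per_factor):
        lam = dil.inoculum_cells[fi] * ab
        wells.append(Well(well_id=well_id, factor_index=fi, cells=rng.poisson(lam)))
    return wells


@dataclass
class CultivationSpec:
    """How founder cells become sequenced read counts.

    ``lottery`` mode draws each well's final composition from a symmetric
    Dirichlet over the taxa present in the inoculum; a small
    ``lottery_concentration`` yields the steep dominance hierarchies
    (one to a few taxa above 1%) that competitive sorting in rich medium
    produces.  ``crm`` mode instead assigns each taxon persistent
    consumer-resource traits and integrates the community ODEs per well.
    Sequencing depth is negative-binomial around ``depth_mean`` with
    shape ``depth_dispersion``; reads are a multinomial draw of that
    depth from the final shares.
    """

    mode: str = "lottery"
    lottery_concentration: float = 0.03
    depth_mean: float = 20000.0
    depth_dispersion: float = 1.2
    crm_config: object = None  # crm.SimulationConfig when mode == "crm"

    def validate(self) -> None:
        if self.mode not in ("lottery", "crm"):
            raise ValueError(f"unknown cultivation mode {self.mode!r}")
        if self.mode == "lottery" and self.lottery_concentration <= 0:
            raise ValueError("lottery_concentration must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")

    def depth_distribution(self) -> stats.rv_discrete:
        """The per-well sequencing-depth law (frozen scipy distribution)."""
        r = self.depth_dispersion
        return stats.nbinom(r, r / (r + self.depth_mean))


def _draw_depth(cult: CultivationSpec, rng: np.random.Generator) -> int:
    r = cult.depth_dispersion
    return int(rng.negative_binomial(r, r / (r + cult.depth_mean)))


def cultivate_and_sequence(
    inocula: list[Well],
    cult: CultivationSpec,
    rng: np.random.Generator | int,
    otu_ids: list[str] | None = None,
) -> OtuTable:
    """Competitive sorting plus sequencing for every well.

    Returns an OTU table with one column per well (well IDs preserved);
    wells whose inoculum was empty yield zero-read columns.
    """
    cult.validate()
    if not inocula:
        raise ValueError("need at least one well")
    if not any(w.cells.sum() > 0 for w in inocula):
        raise ValueError("all wells are empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_otus = len(inocula[0].cells)
    if otu_ids is None:
        otu_ids = [f"OTU_{i + 1}" for i in range(n_otus)]

    crm_traits = None
    if cult.mode == "crm":
        from . import crm as _crm

        cfg = cult.crm_config or _crm.SimulationConfig()
        group_of = rng.choice(_crm.GROUPS, size=n_otus)
        crm_traits = [
            _crm.sample_traits(group_of[i], cfg.n_resources, rng, species_id=otu_ids[i])
            for i in range(n_otus)
        ]

    counts = np.zeros((n_otus, len(inocula)), dtype=np.int64)
    for col, well in enumerate(inocula):
        present = np.flatnonzero(well.cells > 0)
        if present.size == 0:
            continue
        if cult.mode == "lottery":
            shares = rng.dirichlet(
                np.full(present.size, cult.lottery_concentration)
            )
        else:
            from . import crm as _crm

            cfg = cult.crm_config or _crm.SimulationConfig()
            traits = [crm_traits[i] for i in present]
            n0 = well.cells[present].astype(float)
            res = _crm.simulate(
                traits,
                cfg,
                initial_biomass=cfg.inoculum_scale * n0 / n0.sum(),
            )
            shares = res.relative_abundance.to_numpy()
        depth = _draw_depth(cult, rng)
        if depth > 0 and shares.sum() > 0:
            counts[present, col] = rng.multinomial(depth, shares / shares.sum())
    return OtuTable(
        pd.DataFrame(counts, index=otu_ids, columns=[w.well_id for w in inocula])
    )


def generate_campaign(
    raw_spec: RawCommunitySpec | None = None,
    dil_spec: DilutionSpec | None = None,
    cult_spec: CultivationSpec | None = None,
    seed: int | None = None,
) -> tuple[RawCommunity, OtuTable]:
    """End-to-end convenience: raw community -> inocula -> sequenced table.

    When ``seed`` is given it overrides the sub-spec seeds, deriving one
    stream per stage so the whole campaign reproduces from one number.
    """
    raw_spec = raw_spec or RawCommunitySpec()
    dil_spec = dil_spec or DilutionSpec()
    cult_spec = cult_spec or CultivationSpec()
    if seed is not None:
        ss = np.random.SeedSequence(seed)
        s_raw, s_dil, s_cult = ss.spawn(3)
        raw_spec = replace(raw_spec, seed=int(s_raw.generate_state(1)[0] % (2**31)))
        dil_spec = replace(dil_spec, seed=int(s_dil.generate_state(1)[0] % (2**31)))
        cult_rng = np.random.default_rng(s_cult)
    else:
        cult_rng = np.random.default_rng(dil_spec.seed + 1)
    raw = generate_raw_community(raw_spec)
    wells = sample_inocula(raw, dil_spec)
    table = cultivate_and_sequence(wells, cult_spec, cult_rng, otu_ids=raw.otu_ids)
    return raw, table
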