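# Methods

This note documents the models behind `nomvote`, the parameters that
matter, the choices made where the design was genuinely open, and what
the synthetic data can and cannot say about real communities.

## 1. The synthetic dilution-cultivation generator

The generator emulates a dilution-to-extinction culturing study in four
stages, each driven by one master seed.

**Raw community.** Rank abundances are drawn log-normal(0, σ) with
σ = `abundance_shape` (default 1.5) over `n_otus` taxa (default 674) and
sorted.  The top `n_dominant` (16) ranks are rescaled to sum to
`dominant_total_share` (0.6859); if rescaling pushes the smallest head
member below the 1% dominance cut it is blended toward the uniform head
share until it clears 1.05×threshold.  The tail is rescaled to the
complementary mass and capped just below the threshold by water-filling
(capped entries frozen, the remainder rescaled until no entry exceeds
0.99×threshold), so that *exactly* `n_dominant` taxa are dominant.  The
cap is only applicable when `(n_otus − n_dominant) × threshold ≥ 1 −
dominant_total_share`; in tiny communities (e.g. two taxa at a 90/10
split) the tail must exceed 1% somewhere and is left uncapped.  Taxa
below `detection_floor` (default 1e-4 relative abundance) are flagged
*undetected*: they exist and can seed wells but are invisible to
raw-community sequencing.  They are the mechanism by which OTUs later
"appear" in sub-communities.

**Inoculation.** Wells are laid out on 96-well plates
(`P01_A1`-style IDs, 3/4/4 plates for the three dilution factors,
288 + 384 + 384 = 1,056 wells by default).  Each taxon's founder count in
each well is an independent Poisson draw with mean `inoculum_cells ×
true relative abundance` — the standard dilution-to-extinction model in
which occurrence depends on initial abundance.  The expected inoculum
per well is proportional to the dilution factor; the defaults
(200, 100, 20 cells for 1.0e-4, 0.5e-4, 1.0e-5) were chosen once as a
realistic cells-per-160-µL scale that makes per-well richness fall
across the three factors the way observed richness falls in such
experiments.

**Cultivation.** Two modes.  The default `lottery` mode draws each
well's final composition from a symmetric Dirichlet over the taxa
present in its inoculum.  The concentration parameter (default 0.03)
was calibrated by simulation so that wells seeded with a few tens of
taxa usually finish with only 1–6 taxa above the 1% cut — the steep
dominance hierarchy competitive sorting produces in rich medium —
while remaining dependency-free and fast.  The `crm` mode instead gives
every taxon persistent consumer-resource traits (sampled once per
campaign, so taxon identity is meaningful across wells) and integrates
the ODEs of section 2 per well with founder-proportional initial
biomass.  Lottery is the default because cultivation itself is not the
object of inference here; the crm mode exists for mechanistic
coherence.

**Sequencing.** Per-well depth is negative-binomial with mean
`depth_mean` (20,000) and shape `depth_dispersion` (1.2); reads are a
multinomial draw of that depth from the final shares.  The depth law's
lower tail puts roughly 10–15% of wells under the 5,000-read retention
cut, so the depth filter is exercised at a realistic removal rate.
Empty wells yield zero-read columns.

**What the generator does not emulate.** PCR/barcode chemistry,
chimeras, OTU clustering error, taxon-specific cultivability, and any
fitting to real sequencing data.  Tests that pass on this generator
show that the *analysis* stage is correct and that its qualitative
regimes (depth-filter behaviour, richness-vs-dilution monotonicity,
steep dominance, appeared taxa) are reachable; they do not validate the
generator against any particular real community.

## 2. The consumer-resource model

Biomass and resources follow

    dN_i/dt = N_i (g_i Σ_j U_ij R_j − m)
    dR_j/dt = −R_j Σ_i g_i N_i U_ij

Maintenance m (default 0.1 per time unit) is applied **per capita**
(inside the factor N_i).  The printed form of such systems is sometimes
typographically ambiguous; the per-capita reading is the standard
consumer-resource form, keeps N = 0 absorbing, and yields an exact
invariant — with m = 0, d(ΣN + ΣR)/dt = 0 — which the test suite uses
as a solver check (tolerance 1e-6 relative at default settings).
Integration uses LSODA with rtol 1e-8 / atol 1e-10 over t ∈ [0, 100];
states are clipped at zero inside the RHS and clamped after the final
step.  Species ending below `extinction_floor` (1e-9) × initial total
biomass are reported extinct, which suppresses round-off survivors.

**Trait strata.** Growth: high ~ U(0.8, 1.2), low ~ U(0.2, 0.4);
breadth (fraction of resources usable): high ~ U(0.6, 0.9), low ~
U(0.1, 0.3), floored at one resource; uptake entries ~ U(0.5, 1.5) on
usable resources.  The strata are disjoint so group membership (HH, HL,
LH, LL) is meaningful: every HH species out-grows and out-spans every
LL species in the same community.

**Environment.** The resource pool always totals 10 units split equally
across however many resources a level has, so richness levels are
comparable.  The default inoculum is 1e-6 of the resource pool — a
dilute inoculum in rich medium, as in a cultivation well.  This choice
matters: it lengthens the exponential growth window (≈ ln(10⁷) e-folds)
enough that differences in the rare background can accumulate into
different winners.  With a large inoculum the race is over too quickly
for 5% of the biomass to influence anything.

**Step 1, nomination** (80 species, 20 per group, equal biomass, 1/5/10/20
resources, 100 replicates per level by default): the uptake matrix is
populated freely, so metabolic breadth is a raw advantage — more usable
resources means more total uptake.  This mirrors the empirical
observation that dominance-prone taxa carry *more* metabolic genes and
more complete pathways, not the same budget spread thinner.  Outcome:
HH sweeps once resources diversify; at a single resource breadth is
floored for everyone and the high-growth groups (HH, HL) split the
community.

**Steps 2–3, voting and structured rare taxa** (20 HH candidates at 95%
of the inoculum, 60 rare background species from HL/LH/LL at 5%, 10
resources, 100 replicates): here the question is whether *context*
decides among candidates of uniform intrinsic competitiveness, so the
candidates are equalised by construction: growth rate fixed at the HH
midpoint (1.0), breadth fixed at 7 of 10 resources, and the uptake row
normalised to a common budget of 1.  Candidates differ only in *which*
resources they use and how the budget is spread over them.  All rare
species are budget-normalised too — a metabolic trade-off under which a
specialist concentrates its entire uptake capacity on one to three
resources.  That concentration is what gives 5% of the biomass real
leverage over specific resources.  Rare group membership is drawn
uniformly from {HL, LH, LL} per species (an even 20/20/20 split is
available via `even_split=True`).

Under these conditions the winner margin between candidates is thin
(final shares ~0.050 vs 0.054), and the rare draw flips it: several
distinct candidates take Top1 across replicates while rare species
never do (they stay at ~5–7% collectively).

**Structured interference.**  The structured scenario asks whether
dominance can be *steered* by the rare background.  The random campaign
is run first; its Top1 frequencies define per-resource interference
weights

    w_j ∝ (Σ_i freq_i U_ij / max_j)^κ,    κ = 6,

mixed 0.9 : 0.1 with the uniform distribution.  Structured rare species
then both select their usable resources with probability w and
concentrate their uptake budget ∝ w — rare overlap aimed at the
resources the successful candidates rely on.  The `targeted` candidates
are defined as the ones most *exposed* to the interference (largest
U·w); by construction these include the incumbent winners, and the
shielded half are the candidates whose profiles escape the overlap.
With `targeted=0` the bias is disabled and the scenario reproduces the
random campaign exactly (same seed stream).  A fixed a-priori split of
the candidate pool was rejected: when the random-scenario winner
happens to fall in the shielded half, suppressing the targeted half
changes nothing and the comparison is uninformative.  Exposure-based
targeting makes the experiment what it is meant to be — interference
aimed at the incumbents, with the shift measured by the total-variation
distance between the two Top1 frequency vectors and by the
targeted-vs-shielded win split.

**Seeding.** One master seed spawns a dedicated stream for the
candidate pool and one stream per replicate (shared between the paired
random/structured scenarios, so the comparison is paired).

## 3. Occurrence analytics: conventions

* Dominance threshold 1% is **inclusive** (≥); the boundary case is a
  convention, fixed here for determinism.
* Presence means ≥ 1 read after depth filtering; the depth filter is
  strict ("fewer than 5,000 reads" are removed, exactly 5,000 is kept).
* POC is computed from the focal OTU's occurrence count in the
  denominator; because prose like "POC for A to B" is ambiguous, the
  API always reports both directions explicitly (`poc_table` emits
  every ordered pair).
* The pair universe keeps OTUs occurring in strictly more than
  `min_occurrence` (default 10) sub-communities; n retained OTUs give
  n(n−1) ordered pairs.
* Appeared OTUs (absent from the raw profile) count as raw-rare in
  turnover classification.
* A sample is a "D-to-D sub-community" iff its D-to-D abundance share
  strictly exceeds its R-to-D share; ties go to R-to-D (arbitrary but
  fixed; ties are measure-zero on real data).
* Top-N ties break lexicographically by OTU ID.
* POC values are kept at full precision; the two-decimal rounding is
  display only.

## 4. Problem sizes used in the test suite

The acceptance-style tests run the nomination campaign at 25 replicates
per resource level and the voting/structured campaigns at 100
replicates, with synthetic campaigns of 120 wells per dilution factor —
sizes chosen so the whole suite completes in well under a minute of
simulation time while keeping Monte-Carlo margins comfortable (the
checked effects are far from their thresholds: e.g. the structured-rare
total-variation distance is ~0.85 against a 0.1 criterion).

## 5. Known limitations

* The lottery cultivation mode has no taxon-level niche structure:
  recurrent winners arise from inoculum frequency, not traits.  Use the
  crm mode when trait-driven recurrence matters.
* POC on dilution series conflates ecological exclusion with random
  co-loss at strong dilution; the package reports the statistic and its
  categories but does not attempt to de-confound them.
* The ODE model has no cross-feeding, spatial structure, demographic
  noise, or parameter inference; conclusions about rare-taxon voting
  are mechanistic demonstrations, not fits to data.
* Degenerate inputs: zero-read samples must be depth-filtered before
  labelling (enforced with an explicit error); empty profiles are
  skipped in rankings; an all-extinct community reports no Top1.
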