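# Methods

## Constraint-based growth model

An organism is a stoichiometric system *S* (balanced metabolites ×
reactions) with per-reaction flux bounds in mmol·gDW⁻¹·h⁻¹ and a
designated biomass reaction *z*. Growth prediction is standard flux
balance analysis: maximise *z* subject to *S v = 0* and the bounds. The
optimal objective is unique even when the flux vector is not, so all
scores below are well defined.

**Uptake convention.** Import reactions are oriented so that flux ≥ 0
means uptake; an environment is a table of non-negative per-metabolite
uptake limits that map onto import-reaction *upper* bounds. Both readers
normalise reversed exchange reactions on load (SBML convention writes
exchanges in the export direction; the column and bounds are flipped).
A metabolite the model can import but the environment does not provide is
capped at 0 — the environment is exhaustive by definition. Blocking a
metabolite sets its import bound to 0; supplementing raises it to
10⁴ mmol·gDW⁻¹·h⁻¹ (never lowers it below the basal limit).

**Solver.** The LPs are solved with GLPK (via swiglpk). One persistent
problem per model is kept alive across the knockout and supplementation
screens, so successive solves only move column bounds and re-use the
current basis; identical bounds always give identical optima, so results
do not depend on screen order. Correctness of this path is tested against
three independent routes: brute-force vertex enumeration of the flux
polytope on small random networks, scipy's HiGHS-based `linprog`, and
cobrapy's own FBA on a shared model.

**Numerical choices.** Biomass fluxes below 10⁻⁶ count as "no growth"
(models that do not grow in the basal environment are reported and
excluded from scoring, never repaired — gap-filling is out of scope).
Strict-inequality comparisons of fluxes use a relative tolerance of 10⁻⁹
so LP round-off cannot flip a tie.

## Scores

* **MI.** With basal flux *z*, block each environment metabolite *m* in
  turn to get *z′(m)*; *m* is important when *z′/z* < 0.3 (threshold
  configurable). Metabolites outside the model's import map are scored 0
  without a solve — blocking them is a no-op. MI is the Ochiai
  coefficient between the important set and the disease set;
  `ochiai(∅, ·) := 0`, since an empty important set carries no evidence
  of dependence.
* **SGA.** *z*(disease) after supplementing the whole disease set is
  compared with *z*(random) for `n_random = 1000` uniform
  without-replacement draws of equal size from the **whole** basal
  environment — overlap with the disease set is allowed, which makes the
  score conservative (a draw that happens to cover the disease set ties
  and counts against). Ties count against SGA ("strictly less" with the
  10⁻⁹ relative tolerance). Draws touching the same set of import
  reactions provably give the same optimum, so those solves are cached.
* **MR.** The AMH copula C_θ(u,v) = uv / (1 − θ(1−u)(1−v)). θ is fitted
  once per cohort (cohort-level calibration, mirroring the single
  reported cohort correlation) by computing Kendall's τ of the (MI, SGA)
  pairs and inverting τ(θ) = 1 − 2(θ + (1−θ)²ln(1−θ))/(3θ²) by bisection
  on θ ∈ (−1, 1) to 10⁻⁸ (a series expansion handles the removable
  singularity at θ = 0). τ outside the AMH-attainable range
  [(5 − 8 ln 2)/3, 1/3) is clamped to the nearest attainable value and
  flagged in the run metadata. Kendall rather than Spearman correlation
  is used because the AMH family has a closed-form τ–θ relation; MR is
  the copula CDF value itself. Note MR ≤ min(MI, SGA) (Fréchet bound),
  so MR is a conjunction-like score, and on strongly dependent synthetic
  cohorts θ typically clamps at the upper boundary — real cohorts sit
  well inside the range.

Per-model randomness derives from (master seed, model id) via a
blake2-hashed SeedSequence, so a model's SGA is reproducible regardless
of cohort composition or iteration order.

## Evidence curation

A metabolite is classified enriched (depleted) when ≥ `min_studies = 3`
distinct studies report it in that direction. Counting is per direction,
not majority vote: 4 enriched + 1 depleted records → enriched. A
metabolite reaching the threshold in both directions is flagged
conflicting and excluded (the case never arises in the packaged table).
The same study reporting one metabolite in both directions is rejected as
dirty input. Name reconciliation into a model namespace is an explicit
two-column mapping with case-insensitive exact match as fallback;
unmatched names are logged, never silently dropped.

## Ranking enrichment

Walking a score-ranked list top-down, the running sum *W* gains 1/P at a
positive and loses 1/N at a negative; it starts and ends at 0, and
max *W* ∈ [0, 1] summarises how early positives appear. Score ties are
broken by a seeded random shuffle recorded in the run metadata — a
deterministic (e.g. alphabetical) tie-break would bias *W*.

Two Monte-Carlo nulls, 10⁴ permutations each:

1. **Label shuffle** — permute the label sequence, recompute max *W*.
2. **Genus redraw** — draw the observed number of positive genera by
   successive weighted sampling without replacement (weight ∝ genus
   size), relabel exactly those genera positive, recompute max *W* on the
   unchanged ranking. Implemented with exponential Efraimidis–Spirakis
   keys, which is distributionally identical and vectorises.

Empirical p-values use the add-one estimator (1 + #{null ≥ obs})/(1 + n):
never 0, with floor 1/(n+1) ≈ 10⁻⁴ at 10⁴ permutations. Group-level
shifts are tested per score by Mann–Whitney U (exact enumeration for
tie-free groups of ≤ 20, tie-corrected normal approximation otherwise;
two-sided by default with a one-sided switch), and the three scores of a
run form one Benjamini–Hochberg family.

## Blocked case-control abundance analysis

Disease-enriched taxa come from per-study relative-abundance tables with
case/control labels and (study, sub-block) permutation blocks. The
statistic is the sum over blocks of the within-block rank sum of cases
(van-Elteren-style, unstandardised); the null permutes labels within
blocks only; two-sidedness is via |statistic − null mean|. Three
evaluation modes:

* exact enumeration (convolution of per-block rank-sum distributions)
  when the total assignment count is ≤ 2·10⁴;
* Monte-Carlo with the add-one empirical p;
* a moment-based normal approximation using the exact within-block
  permutation mean and sampling-without-replacement variance.

The species-level screen uses the normal mode: its enrichment threshold
(BH-adjusted p < 10⁻⁵) lies far below the Monte-Carlo floor, so only an
analytic tail can reach it — the same reason the established blocked
rank-test implementations default to their asymptotic mode. Species are
first filtered for prevalence (maximum relative abundance > 10⁻³ in ≥ 3
studies); calls are *enriched* if adj p < 10⁻⁵ and AUC > 0.5, *depleted*
if adj p < 5·10⁻² and AUC < 0.5 (the depletion side is deliberately more
permissive — depleted signals are weaker by nature).

## Synthetic data generator

The generator produces every pipeline input with known ground truth. The
defaults are the study conditions used throughout the tests: a
60-metabolite environment with log-uniform uptake limits in [0.1, 100]
and 26 flagged disease metabolites; 200 models in 20 Dirichlet-multinomial
genera, 25% of genera labelled "disease"; dependence strength 0.8 (the
probability a disease-genus model draws each required substrate from the
disease set); substitutability 0.1 (the probability a requirement gains a
redundant partner substrate); 2–5 required substrates per model with
stoichiometries 1–2. Models are import → (convert) → biomass chains whose
biomass is Leontief in the required substrates, so every generated model
grows in the basal environment by construction and blocking a
non-substitutable requirement kills growth outright. Abundance tables are
per-study log-normal (species base log10 mean −3 ± 1, study offsets ± 0.5
as block structure, planted effects as case-side log10 shifts),
renormalised per sample. All randomness flows from one master seed
through named substreams (environment / community / abundance / evidence).

**What passing tests do and do not show.** The toy networks exercise the
pipeline's full contract surface — bound manipulation, degenerate optima,
substitutability, planted dependence — but they are chains, not
genome-scale reconstructions: no cofactor coupling, no realistic biomass
composition, no phylogenetic correlation between genera. Recovery on
synthetic cohorts therefore validates the statistical machinery, not the
biological fidelity of any particular model database.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 20–25 random networks of
≤ 8 reactions for the vertex-enumeration oracle; 100 seeded cases with
environments of 6–12 metabolites and disease sets of ≤ 3 for the
exhaustive-SGA comparison (agreement within 3 binomial standard errors);
5·10⁴ simulated AMH pairs per θ ∈ {−0.5, 0, 0.5, 0.9} for copula
recovery (±0.05); 200 replicates at 499 permutations for null-uniformity
KS checks; and the full default community (200 models, n_random = 1000,
10⁴ permutations) for the positive recovery run, with 20 dependence-0
cohorts at reduced Monte-Carlo depth (n_random = 200, 999 permutations)
for the negative control — the null calibration of a proportion does not
depend on the Monte-Carlo depth, so the reduced depth only widens the
granularity of the reported p-values.

## Known limitations

* The running-sum normalisation (1/P, 1/N increments) reproduces the
  statistic's documented properties, but other normalisations exist and
  would shift max *W* numerically.
* θ is a cohort-level constant; per-taxon dependence structure is not
  modelled.
* The depletion side of the screen is underpowered by design (few
  depleted metabolites reach the evidence threshold), matching the
  enrichment-only focus of the scores.
* Infeasible or non-growing models are excluded, not gap-filled; a
  database with many such models will shrink the scored cohort.
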