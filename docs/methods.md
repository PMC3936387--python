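# Methods

## The system and the question

Litter decomposition in temperate forests is accelerated by
macrodetritivores — here terrestrial isopods — whose per-capita litter
consumption differs strongly among species. Two community-level summaries
of a consumption trait compete as predictors of the process rate: the
community-weighted mean, CWM = Σᵢ pᵢxᵢ (mass ratio hypothesis), and
functional diversity, here functional divergence measured as Rao's
quadratic entropy Q = Σᵢⱼ pᵢpⱼdᵢⱼ (complementarity hypothesis), with pᵢ
the relative abundance of species i and dᵢⱼ a Gower (range-normalised)
trait dissimilarity. Because assemblages with extreme CWM can only be
trait-homogeneous, CWM and Q are hump-dependent, and only a manipulative
design that samples their joint extremes can separate their effects.

## Functional metrics

All metrics operate on one quantitative trait (litter consumption rate,
mg individual⁻¹ day⁻¹) over a fixed species pool:

- **Gower dissimilarity** — dᵢⱼ = |xᵢ − xⱼ| / (max x − min x), the range
  taken over the *whole pool*, not the assemblage, so dissimilarities are
  comparable across assemblages (the convention of trait-ecology
  practice); several traits average their per-trait layers.
- **CWM** — abundance-weighted mean; weights are individual counts, since
  the trait is per-individual consumption. After mortality correction the
  weights may be fractional.
- **Functional divergence** — Rao's Q (both orderings of each pair
  counted). The output column is named `fdiv_rao` to distinguish it from
  the convex-hull divergence index that shares the FDiv acronym.
- **FRic** — in one dimension, the occupied fraction of the pool trait
  range; 0 for monocultures.
- **FEve** — the minimum-spanning-tree evenness; in one dimension the MST
  is the trait-ordered chain. Each adjacent pair contributes
  EWₗ = d(i,j)/(pᵢ+pⱼ); with PEWₗ = EWₗ/ΣEW and S species,
  FEve = (Σ min(PEWₗ, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1)). The index is
  undefined for S < 3 and the function returns NaN there (with a log
  notice) rather than inventing a value.

## Orthogonal design

Candidates are rejection-sampled: a species subset of size 2–4, integer
counts 1–10 per species, accepted iff total fresh biomass (counts × mean
body mass) lies in 0.45–0.65 g. 5000 accepted candidates form the cloud;
duplicates are allowed at this stage. The count cap of 10 matches the
largest count used in the original layout and prevents degenerate
assemblages of many tiny individuals.

**Corner classification.** The four extreme CWM–FD combinations cannot be
cut out with marginal-quantile boxes: in the realised cloud the maximum
CWM among high-Q candidates sits *below* the CWM upper quartile — the
hump again — so a joint upper-quartile box is empty. Corners are instead
scored in rank space: with rank fractions r₁ (CWM) and r₂ (Q), corner HH
scores min(r₁, r₂), HL scores min(r₁, 1−r₂), and so on. Each candidate is
assigned to its best-scoring corner and the top `corner_quantile`
(default 25%) of each corner region keeps the label. Degenerate clouds
still fail loudly: if CWM and Q are perfectly rank-correlated, ties
resolve to HH/LL and the mixed corners come out empty.

**Selection.** Per corner, candidates are drawn in seeded random order;
a candidate is rejected if its Bray–Curtis distance on count vectors to
*any* already-selected assemblage is below `min_composition_distance`
(default 0.10). Identical compositions have distance 0 and can never be
selected twice. The default threshold was set by feasibility: the corner
regions of this 4-species pool are compositionally narrow (the HL corner
contains only *P. scaber*–*A. vulgare* mixtures), and thresholds of
0.12 and above leave some seeds unable to fill all corners, while 0.10
filled 4×4 in 100/100 seeded runs; the original published layout contains
within-corner pairs as close as Bray–Curtis 0.03. Greedy selection can
still dead-end on an unlucky early pick, so the selection restarts with a
fresh seeded shuffle (up to 50 attempts, all derived deterministically
from the design seed) before raising an error.

The selected design reduces but does not eliminate the CWM–Q
interdependence: across 20 seeded runs the mean |Pearson r| over the 16
selected assemblages is ≈ 0.41 versus ≈ 0.45 in the raw cloud. With four
species, one trait, and a biomass window, the achievable corners are not
far enough apart for full orthogonality; this is a property of the study
system, not of the sampler.

## Generative model of an experiment

The synthetic experiment mirrors the published layout: 16 mixed
assemblages × 10 replicates, 4 monocultures × 10, and 10 animal-free
blanks; 7000 ± 250 mg litter; 56 days. For mixed assemblage j, replicate
i:

    deaths ~ per-individual Bernoulli(0.05)
    n_eff  = n_start − ½·n_dead          (deaths uniform in time)
    μ      = β₀ + β_C·CWMᵢⱼ + β_F·Qᵢⱼ + β_S·SRᵢⱼ + uⱼ
    loss%  = μ + ε,  uⱼ ~ N(0, σ_a²),  ε ~ N(0, σ²)

where CWM enters on the cumulative scale (g consumed per individual over
the run: per-day rate × duration / 1000) and all metrics are computed on
n_eff. Defaults are the full-model estimates of the original analysis —
β₀ = 5.012 %, β_C = 98.428 % per (g ind⁻¹), β_F = 4.303 %, β_S = 0.209 %
per species — with residual SD σ = 3.781 %. The between-assemblage SD
σ_a = 2.0 % is a package choice (the original between-assemblage variance
is not recoverable from the published table); it yields an intra-class
correlation of ≈ 0.2, a moderate grouping effect. The isopod loss in mg
is then augmented by a microbial loss, rate × duration with
rate ~ N(30.38, 5.08²) mg day⁻¹ truncated at zero, so the analysis stage
must subtract the background back out. Monocultures draw per-individual
daily rates from N(species mean, species SD) truncated at zero, with dead
individuals feeding for half the run; blanks lose litter microbially
only. Draws whose implied final litter mass would be unphysical are
resampled a bounded number of times.

What the generator does **not** emulate: temporal dynamics within the
run, density dependence of feeding, interactions between isopods and
microbes, and non-Gaussian residuals. Passing tests therefore demonstrate
that the analysis pipeline recovers the assumed linear structure — not
that real decomposition obeys it.

## Analysis pipeline

- % mass loss = 100 (initial − final)/initial.
- Mortality = dead/added; microcosms with mortality **strictly above** 50%
  are excluded.
- Microbial rate = mean over blanks of (initial − final)/duration (or a
  supplied value); isopod consumption = max(0, loss − rate × duration).
- Death correction: effective abundance n_start − ½·n_dead (default) or
  survivors-only via a flag; metrics and richness recomputed on n_eff.
- The response modelled is the **isopod-attributable** % mass loss
  (100 × corrected consumption / initial litter). The subtracted
  background is the *mean* blank rate, so per-microcosm microbial
  variation remains in the residual; fitted residual SDs are accordingly
  larger than the generative σ.
- Mixed models: `statsmodels` MixedLM with a random intercept per
  assemblage, full maximum likelihood (not REML, so log-likelihoods are
  comparable across fixed-effect sets). k = intercept + slopes + 2
  variance components; the null model keeps the random intercept
  (k = 3). Singular fits (σ_a → 0) are reported with σ_a = 0. All 8
  subsets of {CWM, FDiv, SR} are fitted on the kept mixed-assemblage
  records; AICc uses n = number of those records; Akaike weights
  normalise over all 8.
- Simple regressions: one mean response and mean predictor per
  assemblage, OLS per single predictor, two-sided t test for the slope.
  A constant predictor yields NaN rather than an error.

## Numerical and calibration notes

- Biomass is reported in grams at 3 decimals with half-up decimal
  rounding (so 435.5 mg → 0.436 g, matching the published table), after
  suppressing float fuzz at the 10⁻⁶ mg level.
- MixedLM optimisation tries lbfgs, then bfgs, cg and powell, keeping the
  best finite-likelihood converged fit.
- Fixed-effect intervals in the recovery tests use t quantiles with
  between–within degrees of freedom (16 groups − 4 parameters = 12); ML
  standard errors with 16 groups are mildly anticonservative, which is
  expected without REML.
- Model-selection calibration, measured by this suite at the 16 × 10
  scale with only a CWM effect generative: the CWM-only model attains the
  lowest AICc in roughly two-thirds of simulated experiments. This
  matches the theoretical ceiling for AICc with two pure-noise candidate
  predictors — each costs ≈ 2.1 AICc points, and
  P(χ²₁ < 2.13)² ≈ 0.73 — so a substantially higher recovery rate is not
  attainable at this sample size with this model set. The assemblage-mean
  CWM regression is significant (p < 0.05) in the majority of runs while
  the FDiv and SR regressions are not, reproducing the qualitative
  headline pattern.
- The packaged composition table carries the original corner labels,
  which were assigned from *a priori* consumption values that differ from
  the measured monoculture rates; those labels are retained as data but
  are not reproducible from the packaged trait table.

## Known limitations

- Single-trait metrics only; no convex-hull FRic, no categorical traits.
- No REML, random slopes, or multiple-comparison corrections (none were
  used in the analysis this package operationalises).
- The design cannot fully decorrelate CWM and Q for this species pool
  (see above); users supplying richer pools will get closer to true
  orthogonality.
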