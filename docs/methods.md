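# Methods note

This note documents the statistical models, default parameters, numerical
choices and known limitations of the `multistress` package. Quantitative
statements about calibration and recovery refer to quantities computed by
`tests/test_acceptance.py` and `scripts/acceptance.py`.

## 1. Interaction model and taxonomy

Each response is fitted with a 2×2 factorial GLM using treatment coding
(reference cell: non-polluted × ambient):

    g(E[y]) = α + β(w)·W + β(p)·P + β(int)·W·P

Additivity is defined on the link scale g: the additive expectation is
Δadd = β(w) + β(p) and the observed combined effect is
Δobs = Δadd + β(int). Because additivity is scale-dependent, every
classification is specific to the fitted link. For log and logit links,
exp(β(int)) is the interaction ratio (for logit, a ratio of odds ratios);
for the identity link, β(int) itself is the deviation and no
back-transformation is applied.

Classification proceeds in order:

1. **Gate**: if p(int) ≥ alpha_sig (default 0.05) the call is
   "none" / code NA. The gate uses whatever p-value the record carries —
   raw Wald p for ecological fits, BH-adjusted p for genes.
2. **Indeterminate**: if β(int), Δadd or Δobs is exactly zero, no direction
   is assignable. Fitted estimates never land exactly on zero, so this
   branch is reachable only with constructed inputs; classifying it
   "indeterminate" rather than forcing a directional call is a deliberate
   convention, mirrored by the brute-force oracle in the test suite.
3. **Reversal**: sign(Δobs) ≠ sign(Δadd), coded R+/− when Δadd > 0 and
   R−/+ when Δadd < 0 (the code records the direction of the flip).
4. **Synergism vs antagonism**: with same-sign main effects, the
   interaction is synergistic iff it shares that sign (amplification);
   with opposing main effects, iff it reinforces the net additive effect
   (sign(β(int)) = sign(Δadd)). The ± suffix on S/A codes is the sign of
   Δobs — the combined treatment's direction relative to the double
   control — which for non-reversals equals the sign of Δadd.

An equivalent magnitude formulation (synergism ⇔ signs agree; antagonism ⇔
opposite signs with |β(int)| < |Δadd|; reversal ⇔ opposite signs with
|β(int)| > |Δadd|) is used as an independently written oracle in the tests;
the acceptance suite asserts 100% agreement on 10⁴ random triples.

**SESOI / mild flag.** A significant interaction whose Wald CI overlaps a
smallest-effect-size-of-interest band keeps its class but is flagged mild.
On the exp scale the ±5% default gives [0.95, 1.05]. The identity-scale
band is ±(percent/100) × reference_quantity; the reference defaults to
|Δadd| of the same fit in the CLI but is configurable, because the choice
of reference is a reporting decision, not a statistical one.

CI bounds on the exp scale clamp the link-scale argument to ±700 before
exponentiating so extreme (e.g. separated) fits cannot overflow.

## 2. Per-date GLMs

- **Counts** (`count_nb`, log link): NB2 GLM. Dispersion is estimated by
  method of moments from a Poisson pilot, df-corrected by n/(n−k), and
  iterated with GLM refits (4 rounds). Wald SEs are additionally scaled by
  a Pearson overdispersion factor floored at 1 and by the t/normal quantile
  ratio t₀.₉₇₅(n−k)/z₀.₉₇₅. These two scalings exist because naive NB Wald
  tests at the package's design sizes (6 plates/cell, 24 observations) are
  anti-conservative; the acceptance suite verifies a null rejection rate
  inside 5% ± 2.5% over 500 replicates, with p-values passing a KS
  uniformity check. All emitted records satisfy the Wald identity
  p = 2(1 − Φ(|β|/SE)), so p-values remain reconstructible from the table.
- **Binary** (logit): binomial GLM; quasi-separation (|β| > 15 or
  non-finite SEs) raises `DegenerateFitError` with a pointer to the Firth
  fit rather than returning unstable estimates.
- **Firth logistic**: Jeffreys-prior penalized Newton iteration with the
  hat-leverage-adjusted score and step-halving, giving finite estimates
  under complete separation. Implemented in-package because no installed
  library provides it.
- **Proportions** (logit mean link): Beta regression
  (statsmodels `BetaModel`), with the standard (y(n−1)+0.5)/n boundary
  squeeze when values touch 0/1.
- **Continuous** (identity or log): Gaussian GLM with the t-quantile SE
  factor.

Degenerate inputs (constant response, a missing or under-filled treatment
cell, unknown family) raise typed errors instead of producing silent
garbage.

## 3. Season-wide model

The season model is a penalized additive approximation to a GAMM fitted by
penalized IRLS: parametric factorial terms, one centered cubic B-spline
smooth of day per treatment cell (default basis dimension `smooth_df` = 4),
and optional plate random intercepts as a ridge-penalized block.

- The smoothing parameter is selected by GCV over a λ grid of 10^(−2..7)
  with an effective-degrees-of-freedom inflation factor γ = 1.4; the wide
  grid and γ > 1 guard against undersmoothing flat (null) trends.
- The plate-intercept variance uses a Schall-type variance-component
  update, σ²_b = bᵀb / edf_block, iterated with the penalized fit; the
  naive mean(b²) estimator underestimates σ²_b and was observed to
  undercover the factorial coefficients before the change.
- Count responses estimate an NB dispersion from penalized-fit residuals;
  proportion responses use quasi-binomial working weights.

This is a deliberate simplification of an mgcv-style REML GAMM: no exact
REML, no smoothness uncertainty in the SEs, no smooth-specific edf
reporting beyond fitted range summaries. The factorial coefficients — the
quantities the interaction engine consumes — are the supported output.

## 4. Per-gene fits and typing

Genes with total count < 10 are removed before fitting. Counts are
modelled with a log-link NB GLM per gene, sharing one design matrix, with
median-of-ratios size-factor offsets and a vectorized IRLS across genes.

Dispersion: per-gene df-corrected moment estimates from a Poisson pilot
are shrunk **upward only** to a fitted a₀ + a₁/mean trend
(`max(moment, trend)`). One-sided shrinkage is intentional: dispersion
*underestimates* are what inflate the far Wald tail that BH then amplifies
into false discoveries, while overestimates merely cost power. SEs are
then t-calibrated: SE_eff = |β| / Φ⁻¹(T_df(|β|/SE)) with df = n−k
(continuously extended at β → 0 and floored at the raw SE), so that the
normal-reference Wald identity reproduces a t-distributed reference exactly.
The acceptance suite verifies a realized all-null interaction FDR ≤ 0.05
over 40 replicates.

Typing: BH adjustment is applied per design term across retained genes
(per-contrast adjustment, as in standard DE practice; a pooled adjustment
is possible by concatenating columns before `adjust_bh`). Genes with
adjusted interaction p < 0.05 are classified by the same engine applied to
their log2 fold-changes — the taxonomy is invariant to positive rescaling
of all three coefficients, so log2 inputs need no conversion; the per-gene
interaction ratio is reported as 2^lfc_int. Main-effect significance does
not gate classification; only point-estimate signs enter the sign rules.

## 5. Synthetic-data generators: realism and limits

**Survey generator.** Linear predictor
α + β(w)W + β(p)P + β(int)WP + plate intercept + seasonal term, with
per-plate N(0, plate_sd²) intercepts held fixed across dates and a shared
half-period sinusoid (amplitude `smooth_amplitude`, default 0) over the
date range. Families: NB2 counts (Var = μ + φμ²), Bernoulli, Beta with
precision parameter `dispersion`, and Gaussian (clipped at 0 so written
tables satisfy the non-negative schema; defaults keep the clipping
probability negligible). Defaults mirror the package's design template:
6 plates/cell, 7 fortnightly dates. Limits: no treatment-specific seasonal
shapes, no temporal autocorrelation beyond the shared trend and plate
intercepts, no missingness — the generator exists to give downstream
stages a known truth, not to imitate field data closely.

**Gene generator.** Per-gene baseline log2 expression ~ N(6, 2²),
dispersions from the trend φ(μ) = 0.05 + 5/μ, per-sample library-size
factors log-normal (sd 0.15). Each gene draws a type from the mixture (default 80%
null; non-null split 62/29/9% R/A/S, halved per sign variant). Type
templates in log2 units, scaled by `effect_magnitude` and jittered
per-coefficient by U(0.7, 1.3): S± = (±1, ±1, ±1), A± = (±1, ±1, ∓1),
R = (±1, ±1, ∓4). The reversal multiplier 4 guarantees the jittered
interaction still flips the combined effect (worst case 0.7·4 = 2.8 >
1.3·2 = 2.6); the antagonism interaction matches the mains in magnitude so
A genes are as detectable as S genes. The truth table stores each gene's
assigned code and true log2 fold-changes, and a property test asserts the
truth coefficients classify to the assigned code under the shared taxonomy.

**Coefficient generator.** Draws (β, SE) records directly with
self-consistent Wald p-values, for engine-level tests; SEs are sampled
from truncated-positive normals.

All generators derive their streams from `numpy.random.SeedSequence`
spawning (one child per plate / gene), so outputs are bit-for-bit
reproducible under a fixed seed and stable under subsetting.

## 6. Acceptance-study design choices

- Null calibration: 500 survey replicates at 6 plates/cell (the design
  template size), all-null generator (α = 2.0, φ = 0.5); gene null FDR
  over 40 replicates × 300 genes at 7 samples/cell.
- Recovery: the recovery study fixes β(w) = −0.693, β(p) = 2.087,
  β(int) = 0.414 at 50 plates/cell. The baseline and noise level are not
  identified by those coefficients alone, so they were derived once from
  the example study's printed precision (SE(int) = 0.182 at 6 plates/cell
  implies low per-plate noise at baseline counts ≈ e³): α = 3.0, φ = 0.05,
  plate_sd = 0. Gene-mixture recovery uses 1200 genes, 8 samples/cell,
  effect_magnitude = 3.
- `scripts/acceptance.py` spawns independent sub-seed pools per study from
  the single `--seed` (all derived seeds < 2³¹) and writes every quantity
  with its sample size.

## 7. Limitations

- Wald-based inference throughout; no likelihood-ratio or score tests, no
  profile CIs. The SESOI/mild flag is a CI-overlap heuristic, not a formal
  TOST equivalence test.
- The season model approximates, and does not reproduce, REML-based GAMM
  machinery (see the season-model section above).
- Gene dispersion moderation is a simplified, deliberately conservative
  analogue of empirical-Bayes shrinkage; it controls the null FDR at the
  tested sizes but sacrifices some power relative to full EB machinery.
- Classification treats the fitted coefficients as given; uncertainty
  propagates only through the interaction term's p-value and CI, not
  through the signs of the main effects.
- The identity-link SESOI band depends on an externally chosen reference
  quantity; different references change which interactions count as mild.
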