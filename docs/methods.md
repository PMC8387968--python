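# Methods

This note documents the statistical models and procedures implemented in
florastat, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that a
maintainer or reviewer would want spelled out.

## Identification classes and taxonomy handling

The unit of analysis is one identification attempt: a verified species name
and the application's *first* suggested taxon (alternative suggestions are
not scored; an optional hook exists but is off by default).  Scoring compares
the two names after harmonization:

1. tokens after the second are dropped, including rank markers
   (`subsp.`, `var.`, …), collapsing infraspecific taxa to species level;
2. hybrid signs (`×`) are stripped;
3. the synonym table is applied (casefolded lookup, canonical output);
4. comparison is case- and whitespace-insensitive.

The class is **species** on an exact harmonized match, else **genus** when
the genus tokens agree, else **family** when the families agree, else
**none**; an empty suggestion is **none**.  Genus is the first token of the
binomial; family comes from the accepted-name table, with a derived
genus → family map as fallback so that suggestions outside the accepted list
(including genus-level suggestions such as unresolved aggregates) are still
scored at genus/family depth.  A verified name that cannot be resolved to an
accepted species is an error, not a silent `none` — misspelled reference data
should fail loudly.

## Iterated one-per-species subsampling

Species contribute 1–16 photographs; percentages over raw observations would
overweight heavily photographed species.  In each of `n_iterations`
(default 1000) one observation per species is selected uniformly at random;
class percentages are computed over species and averaged across iterations,
with the across-iteration standard deviation /√n as a Monte-Carlo standard
error.  The per-iteration species → class assignment matrix is materialized
once per run and shared by the paired comparison, the grouped cross-table
analyses and the frequency null model, so every analysis of one run sees the
same resamples.

**Paired setting comparison.**  Restricted to species present in both
settings; one observation per species per setting is drawn *independently*
each iteration (the joint draw is not better defined, since the two settings
have disjoint observation pools).  The reported statistic is the share of
iterations in which the field percentage strictly exceeds the database
percentage; ties count as "not higher" and their mass is reported separately.
Shares < 0.05 or > 0.95 are flagged, a symmetric two-tailed reading of the
one-sided exceedance.  Nominally this is a 10 % procedure per class; in
practice it is conservative, because the subsampling spread (one observation
per species) exceeds the sampling spread of the underlying per-species success
profiles whenever species have more than one observation — the realized
per-comparison false-flag rate in the verification study is ≈ 2–3 %.

**Frequency null model.**  Within each iteration, for each class, the median
frequency of the member species is compared with the median of an equally
sized random species set, implemented as a permutation of the class labels
over species.  P per class is the share of iterations with a strictly larger
null median; the reported empirical median is the across-iteration median of
per-iteration medians.  A class empty in every iteration is reported as NaN,
not an error.  Computing the empirical median per iteration (rather than once
on the full data) keeps the comparison within-iteration and therefore
internally consistent with the subsampling; both readings of the procedure
are defensible and this one was chosen.

## Fixed-marginal randomization machinery

Conditional on its margins, a group × class table under independence follows
the multiple hypergeometric law.  The sampler implements Patefield's scheme
from scratch: cells are filled row by row, each cell a conditional
hypergeometric draw given the remaining row quota and remaining column
margins.  The implementation is vectorized across tables (the loop runs over
the r×c cells, not over the sample), which keeps 10⁵ draws of small tables
and 10³ draws of 20×4 tables in the tens of milliseconds.

**Fisher exact test.**  The P value is the total probability of tables no
more probable than the observed one.  Small tables (feasible-table bound
≤ `exact_cap`, default 500) are enumerated exhaustively; larger tables use
the Monte-Carlo estimator `(1 + #{draws with prob ≤ observed}) / (B + 1)`
with `B` = 2000 per subsampling iteration by default.  Log-probabilities are
compared with an absolute tolerance of 1e-9 to keep ties stable; the
enumeration bound is computed in exact integer arithmetic (a floating or
int64 product overflows for realistic margins).  A table with grand total
zero gets P = 1 by convention, logged.

**Cell randomization test.**  The across-iteration averaged table has
non-integer cells; its row and column sums are integerized by
largest-remainder rounding (both margins forced to the same rounded total)
while the observed cell values stay real-valued.  `n_rand` (default 1000)
fixed-margin tables give each cell a mean and SD (ddof = 1); the z-score
`(obs − mean)/sd` is converted to a lower-tail standard normal probability
Φ(z), flagged `higher` above 0.95 and `lower` below 0.05.  A cell whose
randomized values have zero spread gets z = 0, Φ = 0.5 and no flag, logged.
The randomization runs once on the averaged table (per-iteration mode is
available through the underlying functions for sensitivity analysis but is
not the default).

**Group filtering.**  For the family grouping only groups with at least
`min_group_size` species (default 10) are kept; the other trait groupings
use all groups with at least 2 species.  Fewer than two surviving groups is
an error.

## Binomial random-intercept GLMM

Outcome: was the observation identified to species level.  Fixed effects:
organs (reproductive / both / vegetative), focus (single / multiple species)
and background (no vegetation / non-natural / vegetation) under treatment
coding with alphabetically first reference levels.  A Gaussian random
intercept per species absorbs between-species differences; species with
fewer than `min_obs` (default 3) observations are excluded.

The marginal likelihood integrates the random intercept per species with a
Laplace approximation: the per-species mode is found by a damped Newton
iteration (the integrand is strictly log-concave in the intercept), and the
curvature term enters as −½·log(1 + σ²W) with W the summed Bernoulli
weights at the mode.  The outer maximization over (β, log σ) uses L-BFGS-B
with log σ bounded in [−5, 2.5]; starting values come from an ordinary
logistic fit.  Rows are sorted into a canonical order before fitting so the
estimates are invariant to input permutation at machine precision.

The coefficient covariance is the β block of the inverse numerical Hessian
(central differences) of the negative marginal log-likelihood.  Flat
directions — separation, or σ at its boundary — have their curvature floored
at 1e-6 of the largest eigenvalue, which inflates the affected variances
instead of producing an indefinite matrix; the case is logged.  The fit is
cross-checked against lme4's `glmer` (the same Laplace objective) in the
test suite and agrees to a few hundredths of a logit on a well-conditioned
dataset.

Inference: type III Wald chi-square per factor (`bᵀV_b⁻¹b` over the factor's
coefficient block, df = block size); estimated marginal means per factor
level (equal weights over the other factors' levels, random effect at zero,
delta-method SEs); pairwise z contrasts on the logit scale with **Holm**
adjustment within a factor — a deliberate, conservative departure from the
Tukey adjustment common in mixed-model post hoc software, chosen because it
is exact under any dependence and trivially reproducible; compact letters by
the insert-and-absorb algorithm (significant pairs never share a letter,
non-significant pairs always do; minimal letter sets, deterministic given
the level order).  Ordered-class models are deliberately out of scope: with
class frequencies as uneven as real identification data produces, they are
numerically fragile, and the binary outcome carries the substantive question.

## Training-image associations

Per-species success (share of observations at species level, unweighted by
observation count) is correlated with ln(training images) by Pearson
correlation; species with zero recorded training images are excluded from
the ln transform with a logged count.  Group differences in ln(training
images) use a one-factor linear model with a type III F test (identical to
the overall factor test in the one-factor case), group means with model SEs,
Holm-adjusted pairwise contrasts and the same letter display.

## Synthetic-data generator

The generator emulates the statistical structure of a two-setting
identification study, not its biology:

* a species pool with genera nested in families (at least two genera per
  family whenever sizes allow, so family-level matches are constructible),
  growth form / life form / habitat drawn from fixed herb-dominated
  distributions;
* frequency and training images coupled through a latent bivariate Gaussian
  with correlation `freq_train_correlation`; ln(training images) is
  Gaussian (mean 5.5, SD 1.2 on the log scale), frequency a clipped-normal
  on [1, 540] (mean 250, SD 130).  The near-linear frequency marginal keeps
  the realized Pearson correlation within a few hundredths of the configured
  latent correlation (measured 0.890 at a configured 0.9, n = 2000);
* every species appears in the database setting, a `p_field` fraction
  (default 0.5) also in the field; replicate counts are uniform on (1, 16)
  and (1, 5) respectively, mirroring the replicate ranges of the emulated
  design (the uniform is a simplification — real replicate counts are
  right-skewed);
* outcomes follow a sequential (continuation-ratio) model: species-level
  success is Bernoulli on the logit scale with covariate effects, an
  ln(training) slope and a Normal(0, sd_species²) species intercept;
  conditional on failure the genus is correct with probability 0.5, then
  the family with probability 0.55 — defaults that reproduce the familiar
  pattern of ≈ 80 % species, ≈ 90 % ≥ genus, ≈ 95 % ≥ family;
* the first-suggestion name is synthesized to realize the drawn class
  exactly (same-genus species for genus-level outcomes, another genus of
  the same family for family-level ones, an empty suggestion or a
  wrong-family taxon for misses), so re-classification through the data
  model reproduces the truth record verbatim.  When a family has no second
  genus a family-level outcome is demoted to none; the truth record stores
  realized classes, so the round-trip identity is unconditional;
* one master seed feeds named substreams (species table, intercepts, per
  setting: replicates, covariates, outcomes, suggestions), so adding a draw
  never shifts the others, and regeneration is byte-identical.

What it does **not** emulate: real nomenclature and synonymy richness,
geographic structure, phenology, photographer behaviour, or any dependence
of replicate counts on species traits (treated as independent).  Passing
tests therefore demonstrate that the *statistics* behave as designed under a
known generating process — not that any particular application reaches a
particular accuracy on real data.

## Verification studies (scripts/acceptance.py)

The study sizes are design choices balancing Monte-Carlo resolution against
a desktop-scale run (~2 minutes total):

* sampler law: 10⁵ draws of the 2×2 margins (3,2)/(2,3) against the
  closed-form pmf; margins asserted on every draw;
* Fisher Monte-Carlo error: every 2×3 table with grand total ≤ 12
  (18 563 tables) against exhaustive enumeration at B = 10⁴; tables sharing
  margins share the reference sample, which is statistically equivalent and
  keeps the sweep fast;
* cell-flag calibration: 500 independence datasets of 8 groups × 50 species
  with class probabilities (0.4, 0.3, 0.2, 0.1) — sizes chosen so expected
  cells stay ≥ 5 and the normal reading of z is adequate; power: one group's
  species-level probability doubled (0.4 → 0.8), 200 reps;
* paired comparison: 200 null reps (identical generating processes, shared
  replicate-range asymmetry) reporting the per-comparison flag rate over the
  four classes, and 200 power reps with a +20 percentage-point success
  advantage (50 % vs 70 %) for 200 common species;
* GLMM: 20 recovery reps (organ contrast 1.0, σ = 1.0, 150 species × 8
  observations) and 200 null reps (100 species × 6) with a KS test of the
  organ-factor Wald P against uniformity;
* association: 100 reps at 300 species with a planted ln-training slope of
  0.5 — sized by an a-priori power calculation (expected per-species
  Pearson r ≈ 0.4, r-to-z power ≈ 1 at n = 300); the package default slope
  stays at the milder 0.25;
* determinism: the full default pipeline on 300 species run twice and
  compared byte for byte (manifest compared modulo the output path).

## Known limitations

* The Laplace approximation is known to attenuate variance components
  slightly with few observations per group; the recovery study (8 per
  species) measures the bias at ≈ +3 % on σ, negligible here.
* The Monte-Carlo Fisher P has a floor of 1/(B+1); median-P summaries below
  that resolution require raising `fisher_B`.
* The cell-randomization z relies on an approximately normal randomization
  distribution; with expected cells below ~5 the Φ(z) probabilities become
  lumpy and the 0.05/0.95 flags conservative or anticonservative cell by
  cell.
* The paired comparison is a descriptive exceedance share, not a calibrated
  hypothesis test; its conservatism grows with the number of observations
  per species.
* Name harmonization is string-based; it does not consult live taxonomic
  services and resolves only what the supplied synonym table covers.
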