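# Methods

## Exposure model

The dosimetry follows the standard noise-exposure-questionnaire approach:
subjective loudness ratings stand in for sound-level measurements. Each
catalog activity carries a maximum equivalent continuous sound level
(L_Aeq,max, dBA) assigned to rating 5; each rating point below 5 subtracts
10 dB, so the five ratings span a 40-dB range (e.g. a 100-dBA activity maps
5→100, 4→90, 3→80, 2→70, 1→60 dBA). Ratings are elicited once per
activity, not per occasion.

Weekly exposure combines activities by linear-energy (3-dB exchange rate)
averaging:

    L_week = 10·log10( (1/T0) · Σ_i t_i · 10^(L_i/10) )

with t_i = hours/day × days/week. The computation stays in the linear
energy domain until the final logarithm; levels are carried at full double
precision and rounded to one decimal only for display.

**Reference time T0.** The normalization base is a genuinely open choice:
`reference_hours` defaults to 40 h — the occupational reference week
implied by comparing against the 85 dBA occupational permissible limit —
and is configurable (e.g. 168 h for a calendar week, or total exposure time
for a pure time-weighted average). All reported outputs carry the T0 used
in their provenance/config block. Because the choice shifts every level by
a constant, the median weekly level is interpretable only jointly with T0.

**Hazard class.** `hazardous` means L_week strictly greater than
`threshold_dba` (default 85 dBA), matching the ">85 dB" vs "≤85 dB"
dichotomy used in this literature. A respondent with zero noisy leisure
hours has *no* level — represented as an explicit `None`, never 0 dBA,
which is a valid (very quiet) level — and is never hazardous.

**Catalog.** The shipped catalog holds the ten classic leisure activities
of the questionnaire literature (maxima 100–105 dBA) plus three survey
activities without published reference levels, mapped onto acoustically
comparable entries: television → home loudspeakers (100 dBA), video games
→ video arcades (100 dBA), bars → discos (105 dBA). The mapping lives in
the CSV catalog, not in code, so users can substitute their own levels.

## Scoring and classification

Eleven yes/no hearing items score one point per affirmative answer (0–11);
≥4 points classifies probable hearing loss, 0–3 no suspicion. Scores are
banded 0 / 1–3 / 4–6 / 7–11 for reporting. Missing item answers are a
validation error — the score presumes eleven observed answers. Prevalence
confidence intervals default to the Wald (normal-approximation) interval
on the proportion scale with a computed normal quantile (1.959964 at 95%),
which reproduces published prevalence intervals of this questionnaire to
about 0.1 percentage point; Wilson intervals are available by flag since
Wald behaves poorly near 0% and 100%.

## Association statistics

Odds ratios use the cross-product ad/bc. Zero cells receive the
Haldane–Anscombe correction (+0.5 to every cell), flagged in the result;
standard epidemiological practice, and inert on tables without zeros.
Confidence limits are Woolf's: exp(ln OR ± z·√(1/a+1/b+1/c+1/d)). The
chi-square test is the uncorrected Pearson statistic
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with 1 df (Yates by flag; a zero margin
returns NaN, the test being undefined). Confounder adjustment uses the
Mantel–Haenszel pooled estimator Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ) — chosen over
logistic regression as the classical stratified-table analog of a crude
OR; a single stratum reduces exactly to the crude estimate. The
sample-size routine applies the finite-population correction *before* the
design effect (n = ceil(deff · n₀/(1+n₀/N))); the reverse order differs by
a few units on typical survey designs.

All of these are simple closed forms implemented directly; the test suite
cross-checks them against independent implementations (statsmodels
`Table2x2`/`StratifiedTable`, scipy `chi2_contingency`) rather than
delegating to them, so zero-cell policy and quantile conventions stay
under this package's control.

## Synthetic cohort generator

The generator emulates a ~712-respondent university survey: demographics
(59.6% female, ages 18–29 uniform, academic-program mix, 50.3% noisy
residence, 18/730 prior hearing diagnoses), per-activity participation,
log-normal weekly hours split over a categorical number of active days
(hours/day capped at 24 and rounded to 2 decimals, as a survey respondent
would report), and a categorical 1–5 rating per activity. The hazard class
is *derived* by running the exposure model on the sampled records — never
sampled directly — so exposure→symptom coupling flows through the same
code path as a real analysis.

Symptoms are Bernoulli given the hazard class: baseline probability p₀ for
non-hazardous respondents and p₁ = OR·odds₀/(1+OR·odds₀) for hazardous
ones, so the true exposure odds ratio equals the configured target
exactly. Defaults were calibrated once against the emulated study's
published marginals: activity participation/duration/rating distributions
tuned until hazard prevalence ≈ 55% at n = 20 000 (realized 55.1%, median
≈ 86 dBA at T0 = 40 h), mean portable-device use ≈ 18 h/week, television
≈ 10 h, discos ≈ 2 h; symptom baselines solved analytically
(`solve_baseline_probability`) so the hazard-mixture marginals hit the
published prevalences (tinnitus 72%, earache 44%, temporary loss 23%, and
the eleven item marginals 55%…15%).

**Item-level vs score-level association.** Hearing items are conditionally
independent given the hazard class. Eleven items each carrying a modest
odds ratio compound into a much larger odds ratio for the ≥4-point
classification; `induced_probable_loss_or` computes the induced value in
closed form from the Poisson-binomial score tails. The default uniform
per-item OR (1.2102) was solved so the induced score-level OR is ≈1.6,
in the range reported for this exposure–outcome pair.

**What the generator does not emulate.** Conditional independence
under-disperses the symptom score relative to real questionnaires, where
items correlate strongly: the synthetic band distribution has fewer
all-negative and fewer high-score respondents than a real cohort with the
same marginals (e.g. ~1% vs ~7% with zero symptoms). Exposure is also
independent of sex and age, so sex-adjusted and crude odds ratios
coincide in expectation. Passing tests therefore demonstrate correct
dosimetry arithmetic and calibrated association recovery under the stated
model — not that real survey data satisfy these independence assumptions.
An inter-item correlation structure is the natural extension point.

## Pipeline and numerical choices

`run_full_analysis` chains eligibility filtering (consent withheld, prior
hearing diagnosis, age outside [18, 29] — one reason recorded per
exclusion, in that priority order, so retained + excluded always equals
input), exposure, scoring, prevalence, six crude association tables
(hazard class × three ear symptoms and probable hearing loss; female sex
and noisy residence × probable hearing loss), and the sex-stratified
Mantel–Haenszel OR. Reports are timestamp-free JSON plus per-participant
intermediate tables, so fixed inputs give byte-identical output. Display
rounding: odds ratios and CI bounds to 2 decimals, levels to 1,
percentages to the nearest integer.

Problem sizes in the test and acceptance suites were chosen to keep
Monte-Carlo error well inside the asserted bounds at interactive runtimes:
marginal fidelity at n = 20 000 (3 standard errors), Woolf coverage on
1000 simulated tables at the study margins (399/313), parameter recovery
at n = 5000, and null calibration over 100 replicates of n = 5000.

## Known limitations

- Subjective ratings quantize true levels to a 10-dB grid; the model
  inherits that coarseness by design.
- No frequency weighting beyond the catalog's A-weighted levels, no
  exchange rates other than 3 dB, no dose-percent output.
- The Woolf interval is asymptotic; for very sparse tables an exact method
  would be preferable (deliberately out of scope).
- CSV I/O is strict by design: malformed values raise with the offending
  row rather than being coerced.
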