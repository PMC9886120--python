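# leisurenoise

Questionnaire-based leisure-noise dosimetry and hearing-symptom association
analysis for cross-sectional surveys of young adults.

Epidemiologists studying recreational noise-induced hearing loss rarely have
dosimeter measurements. Instead they ask respondents how long they spend on
each noisy leisure activity (personal audio devices, discos, bars, video
games, …) and how loud they perceive it on a 1–5 scale, then convert those
answers into weekly equivalent sound levels and relate the result to
self-reported hearing symptoms. `leisurenoise` implements that entire
pipeline as a tested, reusable library with a CLI, plus a seeded synthetic
cohort generator so every stage can be exercised — and its statistical
calibration verified — without access to any individual survey records.

## The model

**Exposure.** Each activity has a catalog maximum equivalent continuous
sound level L<sub>Aeq,max</sub> (dBA) assigned to rating 5 ("very noisy");
each rating point below 5 subtracts 10 dB:

    L = L_Aeq,max − 10 · (5 − r),   r ∈ {1, …, 5}

Per-activity weekly durations *tᵢ* (hours) and levels *Lᵢ* combine by
energy averaging with a 3-dB exchange rate over a reference time *T₀*
(default: the 40-hour occupational week):

    L_week = 10 · log10( (1/T₀) · Σᵢ tᵢ · 10^(Lᵢ/10) )

A respondent is classified *hazardous* when L_week strictly exceeds the
85 dBA occupational permissible limit.

**Symptoms.** Eleven yes/no hearing-questionnaire items score one point
each (0–11); a score ≥ 4 classifies *probable hearing loss*. Three ear
symptoms (tinnitus, earache, temporary hearing loss after noise) are binary
flags.

**Association.** Exposure × outcome 2×2 tables are summarized by the odds
ratio OR = ad/bc with Woolf confidence limits
exp(ln OR ± z·√(1/a+1/b+1/c+1/d)), the Pearson chi-square test, and the
Mantel–Haenszel pooled odds ratio Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ) for confounder
(e.g. sex) adjustment. The survey sample-size formula
n₀ = z²p(1−p)/d², with finite-population correction n₀/(1+n₀/N) and a
design effect, is also provided.

## Worked example

Generate a 712-respondent synthetic cohort from the shipped configuration
and analyze it:

```bash
leisurenoise generate --seed 42 --n 712 --out cohort.csv
leisurenoise analyze --cohort cohort.csv --out report/
```

`report/report.txt` begins:

```
== Weekly exposure ==
median level: 86.2 dBA (T0=40 h)
hazardous (> 85 dBA): 56%
```

i.e. the median respondent's leisure week carries the same acoustic energy
as 86.2 dBA sustained for 40 h, and 56% of the eligible cohort (696 of the
712 generated respondents pass the eligibility filter; 16 are excluded for
a prior hearing diagnosis) exceed the 85 dBA limit. The association table
reports, per outcome: the 2×2 cells, odds ratio, 95% Woolf interval,
chi-square, and p:

```
probable_hearing_loss,weekly_level_gt_85_dba,227,161,149,159,1.50,1.11,2.03,7.09,0.0077

sex-adjusted (Mantel-Haenszel) OR for probable_hearing_loss: 1.51
```

Respondents above the weekly limit have 1.50 times the odds of probable
hearing loss (95% CI 1.11–2.03, p = 0.008); adjusting for sex barely moves
the estimate (1.51) — as expected, since the generator couples symptoms to
the hazard class, not to sex. The shipped generator defaults were chosen so
the induced probable-hearing-loss odds ratio is ≈1.6 (see
`docs/methods.md`), and that is what the pipeline recovers here within
sampling error. `report/report.json` holds the same numbers
machine-readably, alongside per-participant intermediate tables in
`report/tables/`.

The same analysis runs on real survey exports: any CSV in the documented
wide layout (one row per respondent; `<activity>_hours`, `<activity>_days`,
`<activity>_rating` columns per catalog activity; 1/0-coded symptom items)
is accepted by `leisurenoise analyze` or `leisurenoise.read_cohort`.

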