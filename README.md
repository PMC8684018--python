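# dietpaf

Population attributable fractions (PAFs) and excess cancer cases for
categorical dietary exposures with continuous dose–response relative risks.

`dietpaf` is a reusable burden-of-disease pipeline built around one concrete
analysis: the share of cancers diagnosed in Texas in 2015 attributable to an
inadequate diet — excess red and processed meat consumption, insufficient
fiber intake, and insufficient calcium intake, all acting on colorectal
cancer — stratified by age, sex, and race/ethnicity. It is aimed at
epidemiologists who want to run the same comparative-risk-assessment recipe
on their own exposure prevalence and registry counts, and at anyone who wants
to audit how such headline numbers ("3.3% of cancers are attributable to
inadequate diet") are produced.

## The model

Published relative risks are reported per consumption increment (e.g.
colorectal-cancer RR 1.28 per 100 g/day of red meat in men). They are
converted to a per-unit log-risk slope

    Rg = ln(RR) / x        (detrimental factor, increment x)
    Rg = ln(1/RR) / x      (protective factor)

Consumption is summarized per stratum into categories x = 1..K with
prevalence p_x and median consumption; each category's departure from the
guideline reference level (≤60 g/day red meat, 0 g/day processed meat,
≥28 g/day fiber, ≥1000 mg/day calcium) is

    G_x = max(0, median_x − reference)      (detrimental)
    G_x = max(0, reference − median_x)      (protective)

and the stratum PAF is the Levin-style categorical formula with a
continuous dose–response:

    ERR_x = exp(Rg · G_x) − 1
    PAF   = Σ_x p_x·ERR_x / (1 + Σ_x p_x·ERR_x)

PAFs are computed per exposure-side age band, paired with the cancer
incidence age band ten years older (exposure-to-diagnosis latency),
multiplied by that band's colorectal case count to give excess cases,
aggregated case-weighted over age, combined **additively** over the four
factors, and finally re-expressed against the all-cancer denominator
(all invasive cancers excluding BCC/SCC of the skin).

## Worked example

The analysis is driven by the numbered scripts under `analysis/`:

```sh
python analysis/01_published_inputs.py   # fixtures + slope-conversion check
python analysis/02_headline_burden.py    # headline shares from the published cells
python analysis/03_synthetic_scenario.py # simulate a population, check calibration
python analysis/04_full_pipeline.py      # full pipeline on the synthetic scenario
```

`02_headline_burden.py` combines the published per-factor excess cases
through the engine and prints:

```
persons   :  3428 excess of 103,408 cases -> 3.3% attributable to inadequate diet (published 3.3%)
men       :  1935 excess of  51,472 cases -> 3.8% attributable to inadequate diet (published 3.8%)
women     :  1493 excess of  51,936 cases -> 2.9% attributable to inadequate diet (published 2.9%)
nh_black  :   531 excess of  12,020 cases -> 4.4% attributable to inadequate diet (published 4.4%)
```

i.e. 3,428 cancer cases (3.3% of the 103,408 diagnosed in Texan adults aged
≥25 in 2015) are attributable to inadequate diet, with a higher share in men
than women and in non-Hispanic Blacks than other groups. For colorectal
cancer alone, the four factor PAFs (3.8 + 9.9 + 12.3 + 8.0) combine to
34.0%.

`04_full_pipeline.py` runs the same machinery end to end on a synthetic
population with known ground truth and prints, per factor, the fully refined
categorical PAF against the enumerated individual-level attributable
fraction:

```
red_meat        paf=  4.69%  truth=  4.69%  gap=9.71e-15 pp
```

showing the categorical estimator converges exactly to the Monte-Carlo
oracle at one category per distinct consumption value.

The same pipeline is scriptable from the shell:

```sh
paf fixtures --out data/fixtures
paf simulate --out scratch/demo --seed 7 --n-per-stratum 100
paf run --risk data/fixtures/risk_table1.csv \
        --records scratch/demo/records.csv \
        --incidence scratch/demo/incidence.csv --out results/demo
paf validate --incidence scratch/demo/incidence.csv --strict
```

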