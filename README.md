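# coastsdm

Ensemble species distribution modelling (SDM) for effort-corrected coastal
boat-survey data, with habitat classification and marine protected-area
(MPA) assessment.

The package is aimed at marine ecologists who hold opportunistic
vessel-survey sightings of a mobile top predator (dolphins, in the motivating
system: a coastal *Tursiops aduncus* population around a small East African
MPA) and want to (i) relate occurrence and abundance to environmental
predictors, (ii) map recurrent, occasional and unfavourable habitat, and
(iii) quantify how much of the key habitat an existing protected area
captures. Because such survey data are rarely public, the package ships a
synthetic-data generator that emulates the whole study system with known
truth, so every stage of the pipeline is testable offline.

## The method

Observations are binned onto a 1 km planar grid into cell–season–year strata;
each stratum carries three *ecological measurements* — presence/absence,
number of sightings, summed group size — plus the survey effort (km of
track). Strata with less than 1 km of effort are discarded. The inference
chain is then:

1. **Screening.** Predictors are z-scored; pairs with Spearman |r_s| ≥ 0.7
   are resolved by fitting single-predictor GLMs and keeping the member with
   the lower AIC.
2. **Candidate models.** For each response, every subset of the retained
   predictors is fitted twice: as a GLM (linear terms) and as a GAM (natural
   cubic splines capped at 3 df per term). Presence uses a binomial family
   with logit link; the two count responses use a negative binomial (NB2)
   family, log link, with log(effort) as an offset and the dispersion θ
   estimated by maximum likelihood.
3. **Multimodel inference.** Candidates are ranked by AIC; Akaike weights
   w_m = exp(−Δ_m/2)/Σ exp(−Δ/2) define the 95% confidence set (the smallest
   weight-ranked prefix with cumulative weight > 0.95), and predictions are
   averaged over that set on the response scale.
4. **Evaluation.** A temporal split (train on the first three survey years,
   test on the last) is scored with the concordance index
   (C-index = AUC for binary outcomes), computed per season–year stratum and
   summarized as mean ± SD.
5. **Ensemble.** The GLM-averaged and GAM-averaged surfaces are combined by
   the C-index-weighted consensus WA_i = Σ_j C_j · m_ji / Σ_j C_j.
6. **Habitat & MPA.** Seasonal ensemble surfaces are summarized to per-cell
   mean and SD maps; cells are classified as *recurrent* (mean above the
   grid-wide mean, SD below the grid-wide SD), *occasional* (SD above), or
   *unfavourable* (both below). Abundance is the per-cell product of the
   sightings and group-size ensembles. Category shares and Welch t tests
   compare cells inside vs outside the MPA polygon.

Model checking includes a null-Poisson overdispersion ratio and Moran's I /
spatial correlograms (randomization tests) on the deviance residuals of the
lowest-AIC model.

## Worked example

```python
import pandas as pd
from coastsdm import StudyScenario, run_study

res = run_study(StudyScenario(), seed=1,
                predictors=["BAT", "REEF", "BATH100", "FRONT"],
                screen=False, responses=("presence",))
print(res["evaluation"].round(2).to_string(index=False))
rep = res["mpa_occurrence"]
print("key area inside MPA: %.1f%%" % rep["pct_key_area_inside"])
t = rep["t_tests"]["occurrence"]
print("occurrence inside vs outside: t = %.2f, p = %.2g" % (t["t"], t["p_value"]))
```

prints

```
response    model  ed_train  ed_test  n_vars_best  n_95cs  c_train_mean  c_train_sd  c_test_mean  c_test_sd
presence      GLM     24.08    19.74          4.0     1.0          0.82        0.05         0.79       0.04
presence      GAM     24.46    20.85          4.0     1.0          0.82        0.05         0.79       0.05
presence Ensemble       NaN      NaN          NaN     NaN          0.82        0.05         0.79       0.05
key area inside MPA: 31.4%
occurrence inside vs outside: t = -4.75, p = 1.4e-05
```

Reading the output: the best occurrence GLM explains ~24% of deviance on the
training years and its averaged predictions discriminate presences from
absences with a held-out-year C-index of 0.79 ("moderate-to-good"
discrimination); 31% of the classified key (recurrent + occasional) cells
fall inside the protected polygon, and the mean predicted occurrence is
significantly higher inside than outside (the t statistic is
outside − inside, hence negative).

The library surface is sklearn-shaped where the stage is fit/predict-shaped:
`PredictorStandardizer` and `CollinearityScreener` are transformers,
`SDModel`, `AICModelAverage` and `CIndexWeightedEnsemble` are estimators with
`fit`/`predict` and `get_params`/`set_params`.

## Command line

```sh
coastsdm simulate --config scenario.yaml --seed 3 --out survey/
coastsdm grid --sightings survey/sightings.csv --effort survey/effort.csv \
              --rasters survey/rasters --min-effort 1 --out table.csv
coastsdm classify --stack predictions/ --out habitat.asc
coastsdm assess --habitat habitat.csv --mask mpa.geojson \
                --grid-from habitat.asc --out report.json
```

All artefacts are plain text: CSV tables, ESRI ASCII grids (`.asc`),
GeoJSON masks, YAML scenarios, JSON reports.

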