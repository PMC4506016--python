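"""End-to-end study pipeline.

Chains the whole inference: simulate (or load) a survey, grid it, screen
predictors, fit all-subsets GLM and GAM candidate sets for the three
ecological measurements, model-average within the 95% confidence sets,
evaluate with the temporal C-index split, combine families into a C-index
weighted ensemble, classify habitat, derive abundance, and assess the
protected area.

The pipeline mirrors the published workflow shape: train on the early years,
test on the final year, predict seasonal surfaces for the training period
only, and classify habitat from the mean/SD of those surfaces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ensemble import EnsembleSpec, weighted_average_ensemble
from .gridding import build_cell_season_table
from .habitat import (
    abundance_surface,
    build_mask,
    classify_habitat,
    mpa_comparison,
    prediction_summary,
)
from .models import fit_glm
from .multimodel import fit_all_subsets
from .screening import CollinearityScreener, PredictorStandardizer
from .synthetic import PREDICTORS, StudyScenario, simulate_survey
from .validation import (
    c_index_by_stratum,
    residual_autocorrelation,
    split_by_year,
    summarize_c_index,
)

RESPONSE_FAMILIES = {
    "presence": "binomial",
    "n_sightings": "negbin",
    "group_size_sum": "negbin",
}


def _family_block(
    model_set, train, test, response, reference_effort
) -> dict:
    """Evaluation numbers for one (response, family-form) candidate set."""
    pred_train = model_set.average_predictions(train, reference_effort)
    pred_test = model_set.average_predictions(test, reference_effort)
    c_train = summarize_c_index(
        c_index_by_stratum(train, pred_train, response)
    )
    c_test = summarize_c_index(c_index_by_stratum(test, pred_test, response))
    # explained deviance of the lowest-AIC spec, refitted on each partition
    # and labelled explicitly (the train value is the original fit)
    test_refit = fit_glm(model_set.best.spec, test, offset_col="effort_km")
    ed_test = test_refit.explained_deviance if test_refit.converged else np.nan
    return {
        "model_set": model_set,
        "ed_train": model_set.best.explained_deviance,
        "ed_test": ed_test,
        "n_vars_best": len(model_set.best.spec.predictors),
        "n_95cs": len(model_set.confidence_set()),
        "c_train_mean": c_train[0], "c_train_sd": c_train[1],
        "c_test_mean": c_test[0], "c_test_sd": c_test[1],
        "pred_train": pred_train, "pred_test": pred_test,
    }


def run_response(
    table_train: pd.DataFrame,
    table_test: pd.DataFrame,
    response: str,
    predictors: list[str] | None = None,
    screen: bool = True,
    reference_effort: float = 1.0,
    forms=("glm", "gam"),
) -> dict:
    """Screen, fit, average and evaluate one ecological measurement.

    ``table_train``/``table_test`` must already carry standardized
    predictors.  Returns the per-family blocks plus the C-index-weighted
    ensemble evaluation.
    """
    family = RESPONSE_FAMILIES[response]
    cand = list(predictors) if predictors is not None else [
        c for c in PREDICTORS if c in table_train.columns
    ]
    screener = None
    if screen:
        screener = CollinearityScreener(
            response=response, family=family, predictors=cand,
            offset_col="effort_km",
        ).fit(table_train)
        cand = screener.retained_

    out: dict = {"response": response, "family": family,
                 "screener": screener, "predictors": cand}
    for form in forms:
        ms = fit_all_subsets(
            table_train, cand, response, family, form=form,
            offset_col="effort_km",
        )
        out[form] = _family_block(ms, table_train, table_test, response,
                                  reference_effort)

    # C-index weighted consensus of the family-averaged predictions
    weights = np.array([out[f]["c_train_mean"] for f in forms])
    ens_train = weighted_average_ensemble(EnsembleSpec(
        members=[out[f]["pred_train"] for f in forms],
        c_indices=list(weights), response=response,
    ))
    ens_test = weighted_average_ensemble(EnsembleSpec(
        members=[out[f]["pred_test"] for f in forms],
        c_indices=list(weights), response=response,
    ))
    c_train = summarize_c_index(
        c_index_by_stratum(table_train, ens_train, response)
    )
    c_test = summarize_c_index(
        c_index_by_stratum(table_test, ens_test, response)
    )
    out["ensemble"] = {
        "weights": weights,
        "c_train_mean": c_train[0], "c_train_sd": c_train[1],
        "c_test_mean": c_test[0], "c_test_sd": c_test[1],
    }
    return out


def seasonal_surfaces(
    result: dict,
    env,
    standardizer: PredictorStandardizer,
    season_years,
    reference_effort: float = 1.0,
    forms=("glm", "gam"),
) -> list[np.ndarray]:
    """Ensemble prediction surface per (year, season), over all grid cells."""
    weights = result["ensemble"]["weights"]
    surfaces = []
    for (year, season) in season_years:
        frame = standardizer.transform(env.frame(year, season))
        members = [
            result[f]["model_set"].average_predictions(frame, reference_effort)
            for f in forms
        ]
        surfaces.append(weighted_average_ensemble(EnsembleSpec(
            members=members, c_indices=list(weights),
            response=result["response"],
        )))
    return surfaces


def evaluation_table(results: dict) -> pd.DataFrame:
    """Model-evaluation summary: one row per response and model family."""
    rows = []
    for response, res in results.items():
        for form in ("glm", "gam"):
            blk = res[form]
            rows.append({
                "response": response, "model": form.upper(),
                "ed_train": blk["ed_train"], "ed_test": blk["ed_test"],
                "n_vars_best": blk["n_vars_best"], "n_95cs": blk["n_95cs"],
                "c_train_mean": blk["c_train_mean"],
                "c_train_sd": blk["c_train_sd"],
                "c_test_mean": blk["c_test_mean"],
                "c_test_sd": blk["c_test_sd"],
            })
        ens = res["ensemble"]
        rows.append({
            "response": response, "model": "Ensemble",
            "ed_train": np.nan, "ed_test": np.nan,
            "n_vars_best": np.nan, "n_95cs": np.nan,
            "c_train_mean": ens["c_train_mean"],
            "c_train_sd": ens["c_train_sd"],
            "c_test_mean": ens["c_test_mean"],
            "c_test_sd": ens["c_test_sd"],
        })
    return pd.DataFrame(rows)


def run_study(
    scenario: StudyScenario | None = None,
    seed: int = 0,
    train_years=(2006, 2007, 2008),
    test_years=(2009,),
    predictors: list[str] | None = None,
    screen: bool = True,
    responses=("presence", "n_sightings", "group_size_sum"),
    forms=("glm", "gam"),
    check_residuals: bool = True,
) -> dict:
    """Run the full pipeline on one simulated survey; returns a results dict.

    Keys: ``table`` (modelling frame), ``responses`` (per-response blocks),
    ``evaluation`` (summary table), ``habitat_occurrence`` /
    ``habitat_abundance`` (classified maps), ``abundance_total``,
    ``mpa`` (assessment reports), ``residual_autocorrelation``.
    """
    scenario = scenario or StudyScenario()
    dataset = simulate_survey(scenario, seed=seed)
    table = build_cell_season_table(dataset)
    train, test = split_by_year(table, train_years, test_years)

    standardizer = PredictorStandardizer(
        columns=[c for c in PREDICTORS if c in table.columns]
    ).fit(train)
    train_z = standardizer.transform(train)
    test_z = standardizer.transform(test)
    reference_effort = float(train["effort_km"].mean())

    results = {}
    for response in responses:
        results[response] = run_response(
            train_z, test_z, response, predictors=predictors, screen=screen,
            reference_effort=reference_effort, forms=forms,
        )

    train_schedule = [
        (y, s) for (y, s) in scenario.schedule if y in set(train_years)
    ]
    surfaces = {
        r: seasonal_surfaces(results[r], dataset.env, standardizer,
                             train_schedule, reference_effort, forms=forms)
        for r in responses
    }

    out: dict = {
        "scenario": scenario,
        "dataset": dataset,
        "table": table,
        "train": train_z,
        "test": test_z,
        "reference_effort": reference_effort,
        "responses": results,
        "surfaces": surfaces,
        "evaluation": evaluation_table(results),
    }

    mask = build_mask(scenario.mpa_polygon, scenario.grid)
    out["mpa_mask"] = mask

    if "presence" in responses:
        mean_occ, sd_occ = prediction_summary(surfaces["presence"])
        hab_occ = classify_habitat(mean_occ, sd_occ)
        out["habitat_occurrence"] = hab_occ
        out["occurrence_mean_map"] = mean_occ
        out["mpa_occurrence"] = mpa_comparison(
            hab_occ, mask, surfaces={"occurrence": mean_occ}
        )

    if {"n_sightings", "group_size_sum"} <= set(responses):
        ab_layers = [
            abundance_surface(s, g)[0]
            for s, g in zip(surfaces["n_sightings"], surfaces["group_size_sum"])
        ]
        mean_ab, sd_ab = prediction_summary(ab_layers)
        hab_ab = classify_habitat(mean_ab, sd_ab)
        out["habitat_abundance"] = hab_ab
        out["abundance_mean_map"] = mean_ab
        out["abundance_total"] = float(np.nansum(mean_ab))
        out["abundance_density_mean"] = float(np.nanmean(mean_ab)) / (
            scenario.grid.cell_size ** 2
        )
        out["mpa_abundance"] = mpa_comparison(
            hab_ab, mask, surfaces={"abundance": mean_ab}
        )

    if check_residuals:
        first = responses[0]
        best = results[first]["glm"]["model_set"].best
        out["residual_autocorrelation"] = residual_autocorrelation(
            best, train_z, scenario.grid, n_permutations=199, seed=seed + 1
        )
    return out
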