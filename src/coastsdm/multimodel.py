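"""All-subsets enumeration, Akaike weights and model-averaged prediction.

Candidate models over every subset of the retained predictors are ranked by
AIC.  The Akaike weight of model m is ``exp(-delta_m / 2)`` normalized over
candidates, with ``delta_m = AIC_m - min AIC``; the 95% confidence set is the
smallest prefix of the weight-ranked list whose cumulative weight exceeds
0.95.  Predictions are averaged on the response scale over the confidence
set with weights renormalized within it.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .models import FittedModel, ModelSpec, fit_glm, predict_model

MAX_PREDICTORS = 15


def enumerate_models(
    predictors: list[str],
    response: str,
    family: str,
    form: str = "glm",
) -> list[ModelSpec]:
    """All 2^k predictor subsets (null model included), deterministic order."""
    predictors = list(predictors)
    if len(predictors) > MAX_PREDICTORS:
        raise ValueError(
            f"{len(predictors)} predictors would enumerate "
            f"2^{len(predictors)} models; refusing beyond {MAX_PREDICTORS}"
        )
    specs = []
    for r in range(len(predictors) + 1):
        for subset in combinations(predictors, r):
            specs.append(ModelSpec(response=response, family=family,
                                   predictors=subset, form=form))
    return specs


def akaike_weights(aic: np.ndarray) -> np.ndarray:
    """Akaike weights from AIC values (stable via delta subtraction)."""
    aic = np.asarray(aic, dtype=float)
    finite = np.isfinite(aic)
    if not finite.any():
        raise ValueError("no finite AIC values")
    delta = aic - aic[finite].min()
    rel = np.where(finite, np.exp(-0.5 * delta), 0.0)
    return rel / rel.sum()


class ModelSet:
    """A ranked all-subsets collection with weights and the 95% set.

    Parameters
    ----------
    models : list of FittedModel
        Converged candidates (non-converged candidates should be excluded
        before construction; they carry infinite AIC and zero weight anyway).
    level : float
        Cumulative-weight threshold of the confidence set.
    """

    def __init__(self, models: list[FittedModel], level: float = 0.95):
        if not models:
            raise ValueError("empty model set")
        self.models = list(models)
        self.level = level
        aic = np.array([m.aic for m in self.models])
        w = akaike_weights(aic)
        # rank by weight (descending); deterministic ties via AIC then label
        order = sorted(
            range(len(self.models)),
            key=lambda i: (-w[i], aic[i], self.models[i].spec.label),
        )
        self.order = order
        self.weights = w
        cum = 0.0
        in_set = np.zeros(len(self.models), dtype=bool)
        for i in order:
            # epsilon absorbs float accumulation error at the boundary
            if cum > level + 1e-9:
                break
            in_set[i] = True
            cum += w[i]
        self.in_confidence_set = in_set

    @property
    def best(self) -> FittedModel:
        return self.models[self.order[0]]

    def confidence_set(self) -> list[FittedModel]:
        return [self.models[i] for i in self.order if self.in_confidence_set[i]]

    def confidence_weights(self) -> np.ndarray:
        """Weights of the confidence-set members, renormalized to sum to 1."""
        w = np.array([self.weights[i] for i in self.order
                      if self.in_confidence_set[i]])
        return w / w.sum()

    def ranking(self) -> pd.DataFrame:
        """Ranking table: AIC, delta, weight, cumulative weight, 95CS flag."""
        aic = np.array([m.aic for m in self.models])
        rows = []
        cum = 0.0
        for rank, i in enumerate(self.order, start=1):
            cum += self.weights[i]
            m = self.models[i]
            rows.append({
                "rank": rank,
                "model": m.spec.label,
                "n_terms": len(m.spec.predictors),
                "aic": m.aic,
                "delta": m.aic - aic.min(),
                "weight": self.weights[i],
                "cum_weight": cum,
                "in_95cs": bool(self.in_confidence_set[i]),
                "explained_deviance": m.explained_deviance,
            })
        return pd.DataFrame(rows)

    def average_predictions(
        self, table: pd.DataFrame, reference_effort: float = 1.0
    ) -> np.ndarray:
        """Confidence-set weighted average of response-scale predictions."""
        members = self.confidence_set()
        w = self.confidence_weights()
        preds = np.stack([
            predict_model(m, table, reference_effort) for m in members
        ])
        return np.tensordot(w, preds, axes=1)

    def average_coefficients(self) -> pd.Series:
        """Full-average coefficients over the confidence set (secondary report).

        Terms absent from a member model contribute zero, the "full average"
        convention; spline models are excluded (their coefficients live on
        different bases).
        """
        members = self.confidence_set()
        w = self.confidence_weights()
        all_terms: list[str] = []
        for m in members:
            for t in m.params.index:
                if t not in all_terms:
                    all_terms.append(t)
        out = pd.Series(0.0, index=all_terms)
        for wi, m in zip(w, members):
            out = out.add(wi * m.params.reindex(all_terms, fill_value=0.0))
        return out


def confidence_set(model_set: ModelSet) -> list[FittedModel]:
    """The minimal weight-ranked prefix with cumulative weight > level."""
    return model_set.confidence_set()


def average_predictions(
    model_set: ModelSet, table: pd.DataFrame, reference_effort: float = 1.0
) -> np.ndarray:
    return model_set.average_predictions(table, reference_effort)


def fit_all_subsets(
    table: pd.DataFrame,
    predictors: list[str],
    response: str,
    family: str,
    form: str = "glm",
    offset_col: str | None = None,
    level: float = 0.95,
) -> ModelSet:
    """Fit every predictor subset and return the ranked set.

    Candidates that fail to converge are dropped (their labels are kept on
    the returned set's ``dropped`` attribute).
    """
    specs = enumerate_models(predictors, response, family, form)
    fitted, dropped = [], []
    for spec in specs:
        m = fit_glm(spec, table, offset_col=offset_col)
        if m.converged and np.isfinite(m.aic):
            fitted.append(m)
        else:
            dropped.append(spec.label)
    ms = ModelSet(fitted, level=level)
    ms.dropped = dropped
    return ms


class AICModelAverage(BaseEstimator):
    """All-subsets AIC model averaging as a scikit-learn style estimator.

    ``fit`` enumerates every subset of ``predictors`` (all standard layers
    present in the frame by default), ranks candidates by AIC, and stores the
    95% confidence set; ``predict`` returns the weight-averaged response-scale
    surface.
    """

    def __init__(self, response: str = "presence", family: str = "binomial",
                 form: str = "glm", predictors: list[str] | None = None,
                 offset_col: str = "effort_km", level: float = 0.95):
        self.response = response
        self.family = family
        self.form = form
        self.predictors = predictors
        self.offset_col = offset_col
        self.level = level

    def fit(self, table: pd.DataFrame, y=None):
        from .synthetic import PREDICTORS

        preds = list(self.predictors) if self.predictors is not None else [
            c for c in PREDICTORS if c in table.columns
        ]
        self.model_set_ = fit_all_subsets(
            table, preds, self.response, self.family, form=self.form,
            offset_col=self.offset_col, level=self.level,
        )
        self.ranking_ = self.model_set_.ranking()
        self.n_confidence_set_ = int(self.ranking_["in_95cs"].sum())
        self.best_model_ = self.model_set_.best
        return self

    def predict(self, table: pd.DataFrame, reference_effort: float = 1.0) -> np.ndarray:
        check_is_fitted(self, "model_set_")
        return self.model_set_.average_predictions(table, reference_effort)
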