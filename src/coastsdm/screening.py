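"""Predictor standardization and collinearity screening.

Predictors are z-scored (sample SD) before modelling; collinear pairs are
detected with the Spearman rank correlation at |rs| >= 0.7 and resolved by
comparing single-predictor GLM fits: for each flagged pair the member whose
univariate model has the lower AIC is retained.

Both steps are exposed as scikit-learn style transformers so they can sit in
pipelines and reuse training-time parameters at prediction time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .models import ModelSpec, fit_glm


class PredictorStandardizer(TransformerMixin, BaseEstimator):
    """Column-wise z-scoring with sample standard deviation (ddof=1).

    Training means and SDs are stored at fit time and reapplied to any later
    table (test years, prediction frames), so train and prediction designs
    share one scale.

    Attributes
    ----------
    columns_ : list of str
        Columns standardized (those passed at fit).
    mean_, scale_ : pandas.Series
        Per-column training mean and sample SD.
    """

    def __init__(self, columns: list[str] | None = None):
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        cols = list(self.columns) if self.columns is not None else [
            c for c in X.columns if pd.api.types.is_numeric_dtype(X[c])
        ]
        mean = X[cols].mean()
        scale = X[cols].std(ddof=1)
        zero = scale[(scale == 0) | scale.isna()]
        if len(zero):
            raise ValueError(
                f"zero-variance predictor(s): {sorted(zero.index.tolist())}"
            )
        self.columns_ = cols
        self.mean_ = mean
        self.scale_ = scale
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        out = X.copy()
        out[self.columns_] = (X[self.columns_] - self.mean_) / self.scale_
        return out

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        out = X.copy()
        out[self.columns_] = X[self.columns_] * self.scale_ + self.mean_
        return out


def standardize(table: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, PredictorStandardizer]:
    """z-score ``columns`` of ``table``; returns (table, fitted transformer)."""
    tf = PredictorStandardizer(columns=columns).fit(table)
    return tf.transform(table), tf


def spearman_matrix(predictors: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank-correlation matrix (midranks for ties)."""
    if len(predictors) < 3:
        raise ValueError("need at least 3 rows for a rank correlation")
    cols = list(predictors.columns)
    rho = spearmanr(predictors.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # two columns: scipy returns a scalar
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(rho, index=cols, columns=cols)


def resolve_collinearity(
    matrix: pd.DataFrame,
    table: pd.DataFrame,
    response: str,
    family: str,
    threshold: float = 0.7,
    offset_col: str | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop one member of every highly correlated predictor pair.

    Pairs with |rs| >= ``threshold`` are processed in descending |rs|
    (deterministic tie-break by name); for each pair still alive, two
    univariate GLMs are fitted and the predictor with the higher AIC is
    removed.  AIC ties are broken alphabetically.  Returns the retained
    predictor list and a decision report.
    """
    cols = list(matrix.columns)
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rs = float(matrix.loc[a, b])
            if abs(rs) >= threshold:
                pairs.append((abs(rs), a, b, rs))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    removed: set[str] = set()
    report_rows = []
    for _, a, b, rs in pairs:
        if a in removed or b in removed:
            report_rows.append({
                "pair": f"{a}~{b}", "rs": rs, "aic_a": np.nan, "aic_b": np.nan,
                "decision": "skipped (member already removed)",
            })
            continue
        aic = {}
        for name in (a, b):
            spec = ModelSpec(response=response, family=family,
                             predictors=(name,), form="glm")
            aic[name] = fit_glm(spec, table, offset_col=offset_col).aic
        # lower AIC wins; exact tie falls to the alphabetically first name
        if (aic[a], a) <= (aic[b], b):
            keep, drop = a, b
        else:
            keep, drop = b, a
        removed.add(drop)
        report_rows.append({
            "pair": f"{a}~{b}", "rs": rs, "aic_a": aic[a], "aic_b": aic[b],
            "decision": f"keep {keep}, remove {drop}",
        })
    retained = [c for c in cols if c not in removed]
    report = pd.DataFrame(
        report_rows, columns=["pair", "rs", "aic_a", "aic_b", "decision"]
    )
    return retained, report


class CollinearityScreener(TransformerMixin, BaseEstimator):
    """Spearman |rs| screen resolved by univariate-GLM AIC, per response.

    Parameters
    ----------
    response : str
        Response column in the modelling frame.
    family : {'binomial', 'negbin'}
        GLM family for the univariate deciding fits.
    threshold : float
        Absolute Spearman correlation at or above which a pair is flagged.
    predictors : list of str, optional
        Candidate predictor columns; defaults to the standard ten layers.
    offset_col : str, optional
        Effort column used as a log offset for count families.
    """

    def __init__(self, response: str = "presence", family: str = "binomial",
                 threshold: float = 0.7, predictors: list[str] | None = None,
                 offset_col: str | None = None):
        self.response = response
        self.family = family
        self.threshold = threshold
        self.predictors = predictors
        self.offset_col = offset_col

    def fit(self, table: pd.DataFrame, y=None):
        from .synthetic import PREDICTORS

        cols = list(self.predictors) if self.predictors is not None else [
            c for c in PREDICTORS if c in table.columns
        ]
        self.correlation_ = spearman_matrix(table[cols])
        self.retained_, self.report_ = resolve_collinearity(
            self.correlation_, table, self.response, self.family,
            threshold=self.threshold, offset_col=self.offset_col,
        )
        self.removed_ = [c for c in cols if c not in self.retained_]
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_")
        return table.drop(columns=self.removed_, errors="ignore")
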