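"""Candidate habitat models: GLMs and fixed-df spline GAMs.

Three responses are modelled per stratum of the cell-season-year table:

* ``presence`` — binomial family, logit link;
* ``n_sightings`` and ``group_size_sum`` — negative binomial (NB2) family,
  log link, with ``log(effort_km)`` as an offset so that predictions scale
  with survey effort.

The NB dispersion ``theta`` (= 1/alpha) is estimated by profiling the GLM
log-likelihood over ``log(alpha)``, and counts as one estimated parameter in
AIC.  "GAM" terms are natural cubic splines with exactly 3 degrees of
freedom per predictor, built from training-data quantile knots; with a fixed,
unpenalized basis the df cap is exact and every fit is reproducible, and a
GAM is simply a GLM on the expanded design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

FAMILIES = ("binomial", "negbin")
COUNT_RESPONSES = ("n_sightings", "group_size_sum")
SPLINE_DF = 3


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, family, predictor subset, term form."""

    response: str
    family: str
    predictors: tuple = ()
    form: str = "glm"            # 'glm' (linear terms) or 'gam' (spline terms)
    spline_df: int = SPLINE_DF
    offset: bool | None = None   # None -> offset iff count family

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.form not in ("glm", "gam"):
            raise ValueError(f"unknown form {self.form!r}")

    @property
    def uses_offset(self) -> bool:
        if self.offset is not None:
            return self.offset
        return self.family == "negbin"

    @property
    def label(self) -> str:
        terms = "+".join(self.predictors) if self.predictors else "1"
        return f"{self.response}~{terms}[{self.form}]"


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots).

    With K knots the basis has K-1 columns: x itself plus K-2 curvature
    terms.  Columns are evaluated from the truncated-power representation
    with the natural (linear-tail) constraints absorbed.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = knots.size

    def d(k):
        num = np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - knots[K - 1], 0) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    dK2 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK2)
    return np.column_stack(cols)


def spline_knots(x: np.ndarray, df: int = SPLINE_DF) -> np.ndarray:
    """Quantile knots giving ``df`` basis columns (df+1 knots)."""
    qs = np.linspace(0, 1, df + 1)
    knots = np.quantile(np.asarray(x, dtype=float), qs)
    return np.unique(knots)


def build_design(
    table: pd.DataFrame, spec: ModelSpec, knots: dict | None = None
) -> tuple[np.ndarray, list[str], dict]:
    """Design matrix for a spec; returns (X, column names, knots used).

    For GAM specs, spline knots default to training-data quantiles and are
    returned so prediction frames can reuse them.
    """
    for name in spec.predictors:
        if name not in table.columns:
            raise KeyError(f"predictor {name!r} missing from table")
    cols = [np.ones(len(table))]
    names = ["intercept"]
    used_knots: dict[str, np.ndarray] = {}
    for name in spec.predictors:
        x = table[name].to_numpy(dtype=float)
        if spec.form == "glm":
            cols.append(x)
            names.append(name)
        else:
            kn = (knots or {}).get(name)
            if kn is None:
                kn = spline_knots(x, spec.spline_df)
            used_knots[name] = kn
            if kn.size < 3:  # too few distinct values: degrade to linear
                cols.append(x)
                names.append(name)
                continue
            basis = natural_spline_basis(x, kn)
            for j in range(basis.shape[1]):
                cols.append(basis[:, j])
                names.append(f"s({name}).{j + 1}")
    return np.column_stack(cols), names, used_knots


@dataclass
class FittedModel:
    """A fitted candidate with its likelihood summaries.

    ``aic`` is -2 logLik + 2k with k counting every estimated parameter
    (the NB dispersion included).  ``explained_deviance`` is
    100 * (1 - residual/null deviance).
    """

    spec: ModelSpec
    params: pd.Series
    theta: float | None
    llf: float
    aic: float
    k: int
    deviance: float
    null_deviance: float
    explained_deviance: float
    converged: bool
    n_obs: int
    knots: dict = field(default_factory=dict)
    resid_deviance: np.ndarray | None = None
    fitted_mean: np.ndarray | None = None

    def predict(self, table: pd.DataFrame, reference_effort: float = 1.0) -> np.ndarray:
        return predict_model(self, table, reference_effort)


def _offset_from(table: pd.DataFrame, spec: ModelSpec, offset_col: str | None):
    if not spec.uses_offset:
        return None
    col = offset_col or "effort_km"
    eff = table[col].to_numpy(dtype=float)
    if np.any(eff <= 0):
        raise ValueError("effort must be positive to form a log offset")
    return np.log(eff)


def _profile_negbin(y, X, offset, tol: float = 1e-3):
    """Maximum-likelihood NB2 GLM by profiling log(alpha)."""

    def fit_at(log_alpha: float):
        fam = sm.families.NegativeBinomial(alpha=float(np.exp(log_alpha)))
        return sm.GLM(y, X, family=fam, offset=offset).fit()

    def nll(log_alpha: float) -> float:
        try:
            return -fit_at(log_alpha).llf
        except Exception:
            return np.inf

    opt = minimize_scalar(nll, bounds=(-8.0, 8.0), method="bounded",
                          options={"xatol": tol})
    res = fit_at(opt.x)
    alpha = float(np.exp(opt.x))
    return res, 1.0 / alpha


def fit_glm(
    spec: ModelSpec,
    table: pd.DataFrame,
    offset_col: str | None = None,
    knots: dict | None = None,
) -> FittedModel:
    """Fit one candidate by maximum likelihood.

    Handles both linear (``form='glm'``) and spline (``form='gam'``) designs;
    non-convergence and separation are reported via ``converged`` rather than
    raised, so all-subsets enumeration can continue.
    """
    y = table[spec.response].to_numpy(dtype=float)
    X, names, used_knots = build_design(table, spec, knots)
    offset = _offset_from(table, spec, offset_col)

    theta = None
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if spec.family == "binomial":
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
                k = X.shape[1]
            else:
                res, theta = _profile_negbin(y, X, offset)
                k = X.shape[1] + 1
            converged = bool(getattr(res, "converged", True))
            if not np.all(np.isfinite(res.params)):
                converged = False
            # (quasi-)separation: coefficients diverge on the logit scale
            if spec.family == "binomial" and np.abs(res.params).max() > 30:
                converged = False
        except Exception:
            return FittedModel(
                spec=spec, params=pd.Series(dtype=float), theta=None,
                llf=-np.inf, aic=np.inf, k=X.shape[1], deviance=np.nan,
                null_deviance=np.nan, explained_deviance=np.nan,
                converged=False, n_obs=len(y), knots=used_knots,
            )

    dev = float(res.deviance)
    null_dev = float(res.null_deviance)
    ed = 0.0 if null_dev == 0 else 100.0 * (1.0 - dev / null_dev)
    llf = float(res.llf)
    fm = FittedModel(
        spec=spec,
        params=pd.Series(np.asarray(res.params), index=names),
        theta=theta,
        llf=llf,
        aic=-2.0 * llf + 2.0 * k,
        k=k,
        deviance=dev,
        null_deviance=null_dev,
        explained_deviance=float(np.clip(ed, 0.0, 100.0)),
        converged=converged,
        n_obs=len(y),
        knots=used_knots,
        resid_deviance=np.asarray(res.resid_deviance),
        fitted_mean=np.asarray(res.mu),
    )
    fm._bse = pd.Series(np.asarray(res.bse), index=names)
    return fm


def fit_gam(
    spec: ModelSpec,
    table: pd.DataFrame,
    offset_col: str | None = None,
) -> FittedModel:
    """Fit a spline-term candidate (each smooth capped at 3 df)."""
    if spec.form != "gam":
        spec = ModelSpec(response=spec.response, family=spec.family,
                         predictors=spec.predictors, form="gam",
                         spline_df=spec.spline_df, offset=spec.offset)
    return fit_glm(spec, table, offset_col=offset_col)


def predict_model(
    model: FittedModel, table: pd.DataFrame, reference_effort: float = 1.0
) -> np.ndarray:
    """Response-scale predictions on new rows.

    Probabilities for the binomial family; expected counts scaled to
    ``reference_effort`` km of survey for the negative binomial family.
    """
    X, names, _ = build_design(table, model.spec, knots=model.knots)
    beta = model.params.reindex(names).to_numpy(dtype=float)
    if np.any(np.isnan(beta)):
        raise ValueError("model parameters do not match the design")
    eta = X @ beta
    if model.spec.family == "binomial":
        return expit(eta)
    return float(reference_effort) * np.exp(eta)


def check_overdispersion(
    table: pd.DataFrame, response: str, offset_col: str = "effort_km"
) -> float:
    """Pearson chi-square / df of the null Poisson model (with offset).

    A ratio clearly above 1 indicates overdispersion, motivating the
    negative binomial family; a degenerate all-zero response returns 0.
    """
    y = table[response].to_numpy(dtype=float)
    if np.all(y == 0):
        return 0.0
    X = np.ones((len(y), 1))
    offset = np.log(table[offset_col].to_numpy(dtype=float))
    res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    return float(res.pearson_chi2 / res.df_resid)


class SDModel(BaseEstimator):
    """scikit-learn style wrapper around one candidate habitat model.

    Parameters mirror :class:`ModelSpec`; ``fit`` consumes a modelling frame
    (standardized predictors plus response and effort columns) and ``predict``
    returns response-scale values for new frames.
    """

    def __init__(self, response: str = "presence", family: str = "binomial",
                 predictors: tuple = (), form: str = "glm",
                 spline_df: int = SPLINE_DF, offset_col: str = "effort_km"):
        self.response = response
        self.family = family
        self.predictors = predictors
        self.form = form
        self.spline_df = spline_df
        self.offset_col = offset_col

    def _spec(self) -> ModelSpec:
        return ModelSpec(response=self.response, family=self.family,
                         predictors=tuple(self.predictors), form=self.form,
                         spline_df=self.spline_df)

    def fit(self, table: pd.DataFrame, y=None):
        self.model_ = fit_glm(self._spec(), table, offset_col=self.offset_col)
        self.aic_ = self.model_.aic
        self.explained_deviance_ = self.model_.explained_deviance
        self.coef_ = self.model_.params
        self.theta_ = self.model_.theta
        return self

    def predict(self, table: pd.DataFrame, reference_effort: float = 1.0) -> np.ndarray:
        check_is_fitted(self, "model_")
        return predict_model(self.model_, table, reference_effort)
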