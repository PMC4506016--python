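"""Temporal cross-validation and spatial-autocorrelation diagnostics.

Model skill is measured with the concordance index (C-index): the proportion
of row pairs with different observed outcomes that the predictions rank in
the right order (ties count one half).  For binary outcomes this equals the
area under the ROC curve; for counts it is the natural rank-based analogue,
so one metric serves all three ecological measurements.

Residual spatial structure is checked with global Moran's I under binary
distance-band weights and with a spatial correlogram whose per-class
significance comes from a randomization (permutation) test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def split_by_year(
    table: pd.DataFrame, train_years, test_years
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the modelling frame by survey year (e.g. 70/30 temporal split)."""
    train_years = set(int(y) for y in train_years)
    test_years = set(int(y) for y in test_years)
    if train_years & test_years:
        raise ValueError("train and test years overlap")
    if not train_years or not test_years:
        raise ValueError("train and test year sets must be non-empty")
    years = table["year"].astype(int)
    train = table[years.isin(train_years)].reset_index(drop=True)
    test = table[years.isin(test_years)].reset_index(drop=True)
    return train, test


def c_index(predicted, observed) -> float:
    """Concordance between predictions and outcomes, in [0, 1].

    Over all pairs with unequal observed values: concordant pairs score 1,
    prediction ties 0.5, discordant 0.  Raises if the outcomes are constant
    (no usable pairs).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    # pairwise comparison; strata are small enough for the quadratic form
    do = o[:, None] - o[None, :]
    dp = p[:, None] - p[None, :]
    usable = do != 0
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("outcomes are constant: concordance undefined")
    concordant = (np.sign(dp) == np.sign(do)) & usable
    tied = (dp == 0) & usable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_usable)


def c_index_by_stratum(
    table: pd.DataFrame,
    predicted: np.ndarray,
    response: str,
    by=("season", "year"),
) -> pd.DataFrame:
    """C-index per season-year stratum (strata with constant outcomes skipped)."""
    df = table[[*by, response]].copy()
    df["_pred"] = np.asarray(predicted, dtype=float)
    rows = []
    for key, g in df.groupby(list(by)):
        try:
            c = c_index(g["_pred"].to_numpy(), g[response].to_numpy())
        except ValueError:
            continue
        rows.append({**dict(zip(by, key)), "c_index": c, "n": len(g)})
    return pd.DataFrame(rows)


def summarize_c_index(per_stratum: pd.DataFrame) -> tuple[float, float]:
    """Mean and sample SD of the per-stratum C-index values."""
    c = per_stratum["c_index"].to_numpy()
    if c.size == 0:
        return np.nan, np.nan
    return float(c.mean()), float(c.std(ddof=1)) if c.size > 1 else 0.0


def distance_band_weights(
    coords: np.ndarray, d_min: float = 0.0, d_max: float = 2.0
) -> np.ndarray:
    """Symmetric binary weights: 1 where d_min < distance <= d_max."""
    coords = np.asarray(coords, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    w = ((d > d_min) & (d <= d_max)).astype(float)
    np.fill_diagonal(w, 0.0)
    return w


def morans_i(values, coords=None, weights=None) -> float:
    """Global Moran's I: n/W * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.

    Either a precomputed weight matrix or coordinates (default 0-2 km band,
    i.e. all eight neighbouring 1 km cells) must be supplied.  Constant
    values leave the statistic undefined and raise.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two cells")
    if weights is None:
        if coords is None:
            raise ValueError("supply coords or a weight matrix")
        weights = distance_band_weights(coords)
    w = np.asarray(weights, dtype=float)
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("spatial weights sum to zero")
    z = x - x.mean()
    denom = (z ** 2).sum()
    if denom == 0:
        raise ValueError("values are constant: Moran's I undefined")
    return float(x.size / s0 * (z @ w @ z) / denom)


def spatial_correlogram(
    values,
    coords,
    class_edges,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Moran's I per distance class with randomization-test p-values.

    For each class ``(edges[i], edges[i+1]]`` the statistic uses binary
    distance-band weights; the two-sided permutation p-value is
    ``(1 + #{|I_perm - E| >= |I_obs - E|}) / (1 + n_permutations)`` with
    ``E`` the mean of the permuted statistics (centering keeps the test at
    its nominal level, since Moran's I has null expectation -1/(n-1), not
    zero).  Classes with no pairs are reported with NaN statistics rather
    than failing.
    """
    edges = np.asarray(class_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("class edges must be strictly increasing")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    x = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    n = x.size
    perms = np.stack([rng.permutation(x) for _ in range(n_permutations)])

    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = distance_band_weights(np.asarray(coords, float), d_min=lo, d_max=hi)
        s0 = w.sum()
        if s0 == 0:
            rows.append({"d_lo": lo, "d_hi": hi, "morans_i": np.nan,
                         "p_value": np.nan, "n_pairs": 0})
            continue
        z = x - x.mean()
        denom = (z ** 2).sum()
        i_obs = n / s0 * (z @ w @ z) / denom
        zp = perms - perms.mean(axis=1, keepdims=True)
        denom_p = (zp ** 2).sum(axis=1)
        i_perm = n / s0 * np.einsum("pi,ij,pj->p", zp, w, zp) / denom_p
        center = i_perm.mean()
        p = (1 + np.sum(np.abs(i_perm - center) >= abs(i_obs - center))) / (
            1 + n_permutations)
        rows.append({"d_lo": lo, "d_hi": hi, "morans_i": float(i_obs),
                     "p_value": float(p), "n_pairs": int(s0 / 2)})
    return pd.DataFrame(rows)


def residual_autocorrelation(
    model, table: pd.DataFrame, grid, n_permutations: int = 999, seed: int = 0
) -> dict:
    """Moran's I (with permutation p) on a model's deviance residuals.

    Residuals are aggregated to cell means over strata, then tested on cell
    centers with the default 0-2 km neighbour band.
    """
    resid = pd.Series(model.resid_deviance, index=table.index)
    per_cell = resid.groupby(table["cell_id"]).mean()
    coords = grid.cell_centers()[per_cell.index.to_numpy(dtype=int)]
    w = distance_band_weights(coords)
    i_obs = morans_i(per_cell.to_numpy(), weights=w)
    rng = np.random.default_rng(seed)
    x = per_cell.to_numpy()
    i_perm = np.array([
        morans_i(rng.permutation(x), weights=w) for _ in range(n_permutations)
    ])
    center = i_perm.mean()
    count = int(np.sum(np.abs(i_perm - center) >= abs(i_obs - center)))
    return {
        "morans_i": i_obs,
        "p_value": (1 + count) / (1 + n_permutations),
        "n_cells": int(per_cell.size),
    }
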