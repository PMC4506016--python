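"""C-index weighted consensus of prediction surfaces.

The ensemble surface is the weighted average of member surfaces with weights
proportional to each member's pre-evaluated concordance index:

    WA_i = sum_j(C_j * m_ji) / sum_j C_j

Members here are the GLM- and GAM-averaged surfaces for one response, each
weighted by its training-data mean C-index; the result is a convex
combination, so probability surfaces stay in [0, 1] and count surfaces
stay non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


@dataclass
class EnsembleSpec:
    """Member surfaces (aligned cell-for-cell) and their C-index weights."""

    members: list          # list of per-cell arrays, one per member
    c_indices: list        # pre-evaluated C-index per member, each in (0, 1]
    response: str = ""

    def validate(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")
        if len(self.members) != len(self.c_indices):
            raise ValueError("one C-index per member surface is required")
        shapes = {np.asarray(m).shape for m in self.members}
        if len(shapes) != 1:
            raise ValueError("member surfaces are not aligned cell-for-cell")
        c = np.asarray(self.c_indices, dtype=float)
        if np.any(c <= 0) or np.any(c > 1):
            raise ValueError("C-index weights must lie in (0, 1]")


def weighted_average_ensemble(spec: EnsembleSpec) -> np.ndarray:
    """Per-cell C-index-weighted average of the member surfaces."""
    spec.validate()
    c = np.asarray(spec.c_indices, dtype=float)
    stack = np.stack([np.asarray(m, dtype=float) for m in spec.members])
    return np.tensordot(c / c.sum(), stack, axes=1)


class CIndexWeightedEnsemble(BaseEstimator):
    """Consensus of fitted prediction models, weighted by held-out skill.

    Parameters
    ----------
    members : list
        Fitted objects exposing ``predict(table, reference_effort)`` (e.g.
        :class:`~coastsdm.multimodel.AICModelAverage` instances).
    c_indices : list of float, optional
        Pre-evaluated C-index per member.  If omitted, ``fit`` evaluates each
        member on the supplied frame with the package C-index.
    response : str
        Response column used when evaluating members at fit time.
    """

    def __init__(self, members=None, c_indices=None, response: str = "presence"):
        self.members = members
        self.c_indices = c_indices
        self.response = response

    def fit(self, table=None, y=None, reference_effort: float = 1.0):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.c_indices is not None:
            c = list(self.c_indices)
        else:
            from .validation import c_index

            if table is None:
                raise ValueError("supply an evaluation frame or c_indices")
            obs = table[self.response].to_numpy()
            c = [
                c_index(m.predict(table, reference_effort), obs)
                for m in self.members
            ]
        c_arr = np.asarray(c, dtype=float)
        if np.any(c_arr <= 0):
            raise ValueError("member C-index weights must be positive")
        self.weights_ = c_arr / c_arr.sum()
        self.member_c_indices_ = c_arr
        return self

    def predict(self, table, reference_effort: float = 1.0) -> np.ndarray:
        check_is_fitted(self, "weights_")
        preds = np.stack([
            np.asarray(m.predict(table, reference_effort), dtype=float)
            for m in self.members
        ])
        return np.tensordot(self.weights_, preds, axes=1)
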