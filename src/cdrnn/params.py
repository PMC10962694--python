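"""Mixed-effects parameter composition: ``v = v0 + V z``.

Every model parameter (network weights, coefficients, distribution biases)
conceptually lives in one long vector ``v``. Its fixed part ``v0`` is shared
across all observations; the random part is ``V z``, where ``V`` is a
``V x Z`` matrix of per-level deviations whose rows sum to zero within each
grouping factor, and ``z`` is a binary indicator selecting the levels that
apply to one response sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ParameterStore:
    """Fixed vector ``v0`` plus random-effects matrix realizing ``v = v0 + Vz``.

    Attributes
    ----------
    v0 : ndarray, shape (V,)
    V_mat : ndarray, shape (V, Z)
        Columns are random-effects levels, grouped by factor.
    grouping_map : dict
        ``factor name -> array of column indices`` belonging to that factor.
    ranef_scope : ndarray of bool, shape (V,), optional
        Rows (parameters) allowed to vary randomly; rows outside the scope
        are forced to zero in ``V_mat``.
    """

    v0: np.ndarray
    V_mat: np.ndarray
    grouping_map: dict
    ranef_scope: np.ndarray = field(default=None)

    def __post_init__(self):
        self.v0 = np.asarray(self.v0, dtype=float)
        self.V_mat = np.asarray(self.V_mat, dtype=float)
        if self.V_mat.shape[0] != self.v0.shape[0]:
            raise ValueError("V_mat row count must match len(v0)")
        cols = np.concatenate(
            [np.asarray(ix, dtype=int) for ix in self.grouping_map.values()]
        ) if self.grouping_map else np.empty(0, dtype=int)
        if len(cols) != self.V_mat.shape[1] or (
            len(cols) and set(cols.tolist()) != set(range(self.V_mat.shape[1]))
        ):
            raise ValueError("grouping_map must partition the columns of V_mat")
        if self.ranef_scope is not None:
            self.ranef_scope = np.asarray(self.ranef_scope, dtype=bool)
            self.V_mat[~self.ranef_scope, :] = 0.0

    def compose(self, z: np.ndarray) -> np.ndarray:
        """Effective parameter vector for indicator ``z``."""
        return compose_params(self.v0, self.V_mat, z)

    def center(self) -> None:
        """Project rows to zero sum within each factor's column block, in place."""
        self.V_mat = center_ranef(self.V_mat, self.grouping_map)


def compose_params(v0: np.ndarray, V_mat: np.ndarray, z: np.ndarray) -> np.ndarray:
    """``v = v0 + V z``: add the random deviations selected by indicator ``z``.

    Equivalent to indexing and summing the deviation columns of all active
    levels. ``z = 0`` returns the population-level vector ``v0``.
    """
    v0 = np.asarray(v0, dtype=float)
    V_mat = np.asarray(V_mat, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.shape[0] != V_mat.shape[1]:
        raise ValueError(
            f"indicator has length {z.shape[0]}, V_mat has {V_mat.shape[1]} columns"
        )
    return v0 + V_mat @ z


def center_ranef(V_mat: np.ndarray, grouping_map: dict) -> np.ndarray:
    """Remove the per-row mean within each grouping factor's column block.

    After centering, the deviations of each parameter across the levels of
    any one factor sum to zero, so averaging over levels recovers the fixed
    effect. The projection is idempotent.
    """
    out = np.array(V_mat, dtype=float, copy=True)
    for cols in grouping_map.values():
        cols = np.asarray(cols, dtype=int)
        if cols.size:
            out[:, cols] -= out[:, cols].mean(axis=1, keepdims=True)
    return out
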