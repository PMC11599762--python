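"""Test/retest functional fingerprinting via differential identifiability.

The identifiability matrix ``A`` is an ``S x S`` (generally non-symmetric)
matrix of Pearson correlations between each subject's test-session static
connectivity vector and every subject's retest vector.  Its diagonal mean is
the self-identifiability ``I_self``, the off-diagonal mean is ``I_others``,
and the differential identifiability is

    I_diff = (I_self - I_others) * 100    [percentage points]

Network-restricted scores re-run the computation on the features selected by a
functional-network mask; a subsampling variant repeats the score over random
subject subsets drawn without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import NETWORKS, NetworkAssignment, StaticConnectivity, network_mask
from .errors import DegenerateSignalError, DimensionError

__all__ = [
    "IdentifiabilityMatrix",
    "identifiability_matrix",
    "differential_identifiability",
    "network_identifiability",
]


@dataclass
class IdentifiabilityMatrix:
    """S x S test-vs-retest similarity matrix (rows = test subjects)."""

    values: np.ndarray
    method: str = ""
    mask_description: str = "whole-brain"

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=np.float64)
    return np.vstack([f.values if isinstance(f, StaticConnectivity) else np.asarray(f)
                      for f in features])


def identifiability_matrix(test, retest, mask: np.ndarray | None = None,
                           method: str = "",
                           mask_description: str = "whole-brain") -> IdentifiabilityMatrix:
    """Pearson correlations between test rows and retest rows.

    ``test`` and ``retest`` may be ``(S, F)`` arrays or sequences of
    :class:`~hobrain.connectivity.StaticConnectivity` in the same subject
    order.  An optional boolean feature ``mask`` is applied to both sessions.
    """
    x = _as_matrix(test)
    y = _as_matrix(retest)
    if x.shape != y.shape:
        raise DimensionError("test and retest feature matrices differ in shape")
    if mask is not None:
        if mask.size != x.shape[1]:
            raise DimensionError("mask length does not match feature count")
        x, y = x[:, mask], y[:, mask]
    if x.shape[1] < 2:
        raise DimensionError("need at least 2 features for correlations")
    for name, m in (("test", x), ("retest", y)):
        flat = np.flatnonzero(m.std(axis=1) == 0.0)
        if flat.size:
            raise DegenerateSignalError(
                f"constant masked feature vector for {name} subject {int(flat[0])}")
    xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    ys = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, keepdims=True)
    a = xs @ ys.T / x.shape[1]
    return IdentifiabilityMatrix(np.clip(a, -1.0, 1.0), method=method,
                                 mask_description=mask_description)


def differential_identifiability(a: IdentifiabilityMatrix) -> tuple[float, float, float]:
    """``(I_self, I_others, I_diff)`` with I_diff on the percent scale."""
    m = a.values
    s = m.shape[0]
    if s < 2:
        raise DimensionError("need at least 2 subjects")
    i_self = float(np.mean(np.diag(m)))
    off = ~np.eye(s, dtype=bool)
    i_others = float(np.mean(m[off]))
    return i_self, i_others, (i_self - i_others) * 100.0


def network_identifiability(test, retest,
                            feature_index: list[tuple[int, ...]],
                            assignment: NetworkAssignment,
                            mode: str = "at_least_one",
                            method: str = "",
                            n_subsample: int | None = None,
                            n_rep: int = 100,
                            seed: int = 0) -> pd.DataFrame:
    """Per-network I_diff table, optionally over subject subsamples.

    When ``n_subsample`` is given, ``n_rep`` random subject subsets of that
    size are drawn without replacement and the table reports the mean and
    standard deviation of I_diff over the draws (whole-cohort otherwise).
    """
    x = _as_matrix(test)
    y = _as_matrix(retest)
    rows = []
    rng = np.random.default_rng(seed)
    for network in NETWORKS:
        msk = network_mask(feature_index, assignment, network, mode=mode)
        if not msk.any():
            raise DimensionError(f"network {network} selects no features")
        if n_subsample is None:
            a = identifiability_matrix(x, y, mask=msk, method=method,
                                       mask_description=f"{network}/{mode}")
            i_self, i_others, i_diff = differential_identifiability(a)
            rows.append({"network": network, "I_self": i_self,
                         "I_others": i_others, "I_diff": i_diff})
        else:
            if n_subsample > x.shape[0]:
                raise DimensionError("subsample larger than the cohort")
            vals = []
            for _ in range(n_rep):
                sel = rng.choice(x.shape[0], size=n_subsample, replace=False)
                a = identifiability_matrix(x[sel], y[sel], mask=msk, method=method)
                vals.append(differential_identifiability(a)[2])
            vals = np.asarray(vals)
            rows.append({"network": network, "I_diff": float(vals.mean()),
                         "I_diff_sd": float(vals.std(ddof=1)) if n_rep > 1 else np.nan})
    return pd.DataFrame(rows)
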