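"""Region-by-time signal panels: containers, z-scoring and Pearson functional connectivity.

A :class:`TimeSeriesPanel` holds an ``N x T`` real matrix of parcellated brain
signals (one row per region).  All statistics here use the population standard
deviation (``ddof=0``); this is what makes the temporal-unwrapping identity for
edge time series exact: the time mean of the raw product of two z-scored rows
equals their Pearson correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSignalError, DimensionError

__all__ = ["TimeSeriesPanel", "zscore_panel", "pearson_fc"]


@dataclass
class TimeSeriesPanel:
    """An ``N x T`` matrix of region signals with region labels.

    Parameters
    ----------
    values : ndarray, shape (N, T)
        One row per region; finite entries.
    region_labels : list of str, optional
        Defaults to ``R000, R001, ...``.
    """

    values: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError("panel values must be a 2-D region x time matrix")
        if self.values.shape[1] == 0:
            raise DimensionError("panel must have at least one time frame")
        if not np.all(np.isfinite(self.values)):
            raise DimensionError("panel contains non-finite entries")
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(self.values.shape[0])]
        if len(self.region_labels) != self.values.shape[0]:
            raise DimensionError(
                f"{len(self.region_labels)} labels for {self.values.shape[0]} regions"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise DimensionError("duplicate region labels")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def is_zscored(self, tol: float = 1e-10) -> bool:
        mu = self.values.mean(axis=1)
        sd = self.values.std(axis=1)
        return bool(np.all(np.abs(mu) < tol) and np.all(np.abs(sd - 1.0) < tol))


def zscore_panel(panel: TimeSeriesPanel) -> TimeSeriesPanel:
    """Row-wise z-scoring ``(x - mu) / sigma`` with population sigma (ddof 0).

    Raises
    ------
    DegenerateSignalError
        If any row is constant, naming the offending region.
    """
    mu = panel.values.mean(axis=1, keepdims=True)
    sd = panel.values.std(axis=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0.0)
    if zero.size:
        names = ", ".join(panel.region_labels[i] for i in zero[:5])
        raise DegenerateSignalError(
            f"constant signal (zero variance) for region(s): {names}"
        )
    return TimeSeriesPanel((panel.values - mu) / sd, list(panel.region_labels))


def pearson_fc(panel: TimeSeriesPanel) -> np.ndarray:
    """Pearson functional connectivity: the ``N x N`` correlation matrix of the rows.

    Symmetric with unit diagonal; entries clipped into ``[-1, 1]`` against
    floating-point overshoot.
    """
    if panel.n_frames < 2:
        raise DimensionError("need at least 2 frames for correlations")
    sd = panel.values.std(axis=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        names = ", ".join(panel.region_labels[i] for i in zero[:5])
        raise DegenerateSignalError(f"zero-variance region(s): {names}")
    fc = np.corrcoef(panel.values)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return fc
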