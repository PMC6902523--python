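"""Grid-image representation of vital-sign series and channel fusion.

A series of T timestamped points is mapped onto an m x n grid over its
time-value bounding box: the time axis is split into n equal-width columns,
the value axis into m equal-height rows, and cell (i, j) counts the points
falling in that rectangle (row 0 = lowest values, column 0 = earliest times).
Every point lands in exactly one rectangle, so the counts sum to T.  The five
channels of a patient are stacked into a (5, m, n) tensor — the image a
convolutional network classifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import INDICATORS, PatientRecord, VitalSeries

#: fixed channel order of fused tensors
CHANNEL_ORDER = INDICATORS


@dataclass
class GridMatrix:
    """m x n point counts of one series, with the bounds that defined the grid."""

    counts: np.ndarray
    value_bounds: tuple[float, float]
    time_bounds: tuple[float, float]
    indicator: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class GridTensor:
    """Five stacked channel grids of one patient, shape (5, m, n)."""

    data: np.ndarray
    patient_id: str
    normalized: bool

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def _bin_index(x: np.ndarray, lo: float, hi: float, nbins: int) -> np.ndarray:
    """Half-open equal bins [lo, hi); the last bin is closed so hi is counted.

    Bin edges are materialized as lo + (hi - lo) * i / nbins so that a point
    sitting exactly on an edge goes to the upper bin, reproducibly.  A
    degenerate range (lo == hi) puts every point in bin 0.
    """
    if hi == lo:
        return np.zeros(len(x), dtype=int)
    edges = lo + (hi - lo) * np.arange(1, nbins) / nbins
    idx = np.searchsorted(edges, x, side="right")
    return np.clip(idx, 0, nbins - 1)


def grid_represent(
    series: VitalSeries,
    m: int,
    n: int,
    value_bounds: tuple[float, float] | None = None,
    time_bounds: tuple[float, float] | None = None,
) -> GridMatrix:
    """Count the points of a series on an m x n grid.

    Bounds default to the series' own min/max (per-series grids); pass
    explicit bounds for cross-patient comparability.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    if len(series) < 1:
        raise ValueError("cannot grid an empty series")
    v_lo, v_hi = value_bounds or (float(series.values.min()), float(series.values.max()))
    t_lo, t_hi = time_bounds or (float(series.times.min()), float(series.times.max()))
    rows = _bin_index(series.values, v_lo, v_hi, m)
    cols = _bin_index(series.times, t_lo, t_hi, n)
    counts = np.zeros((m, n), dtype=int)
    np.add.at(counts, (rows, cols), 1)
    return GridMatrix(counts, (v_lo, v_hi), (t_lo, t_hi), series.indicator)


def fuse_channels(
    record: PatientRecord, m: int = 16, n: int = 16, normalize: bool = True
) -> GridTensor:
    """Stack the five channel grids of a patient into a (5, m, n) tensor.

    Channel order is fixed by :data:`CHANNEL_ORDER` regardless of the input
    map's ordering.  With ``normalize`` (default), each channel is divided by
    its maximum cell count, giving values in [0, 1] for training stability;
    without it the tensor holds raw integer counts (channel c sums to T_c).
    """
    missing = record.missing_indicators
    if missing:
        raise ValueError(f"record {record.patient_id!r} missing {missing[0]!r}")
    planes = []
    for ind in CHANNEL_ORDER:
        g = grid_represent(record.series[ind], m, n).counts.astype(float)
        if normalize and g.max() > 0:
            g = g / g.max()
        planes.append(g)
    return GridTensor(np.stack(planes), record.patient_id, normalize)


def cohort_tensors(cohort, m: int = 16, n: int = 16, normalize: bool = True):
    """(X, y, ids) arrays for a cohort's complete records."""
    records = cohort.complete_records()
    X = np.stack([fuse_channels(r, m, n, normalize).data for r in records])
    y = np.array([r.label for r in records], dtype=int)
    ids = [r.patient_id for r in records]
    return X, y, ids
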