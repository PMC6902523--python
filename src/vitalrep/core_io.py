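"""Data model, CSV I/O and shared preprocessing for intraoperative vital-sign series.

The unit of analysis is one surgical patient monitored over one operation on
five non-invasive channels: heart rate (``hr``, bpm), systolic and diastolic
blood pressure (``nisysbp`` / ``nidiasbp``, mmHg), oxygen saturation
(``spo2``, %) and pulse pressure (``pp`` = systolic - diastolic, mmHg).
Series are kept as irregular timestamped points; nothing here interpolates.

On-disk formats are deliberately plain:

* series CSV  -- header ``patient_id,indicator,t_seconds,value``
* labels CSV  -- header ``patient_id,label`` with label in {0, 1}
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical channel order used by every pipeline in the package.
INDICATORS: tuple[str, ...] = ("hr", "nisysbp", "nidiasbp", "spo2", "pp")

SERIES_COLUMNS = ("patient_id", "indicator", "t_seconds", "value")
LABEL_COLUMNS = ("patient_id", "label")


@dataclass
class VitalSeries:
    """One indicator's timestamped measurement sequence for one patient.

    Parameters
    ----------
    indicator : str
        One of :data:`INDICATORS`.
    times : ndarray
        Seconds since series start, strictly increasing.
    values : ndarray
        Measurements, same length as ``times``.
    """

    indicator: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.indicator not in INDICATORS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if len(self.times) < 1:
            raise ValueError("series must contain at least one point")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.indicator == "spo2" and (
            np.any(self.values < 0) or np.any(self.values > 100)
        ):
            raise ValueError("spo2 values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.times)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VitalSeries):
            return NotImplemented
        return (
            self.indicator == other.indicator
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class PatientRecord:
    """Labelled bundle of the five indicator series for one patient."""

    patient_id: str
    label: int
    series: dict[str, VitalSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def is_complete(self) -> bool:
        """True when all five indicators are present."""
        return all(ind in self.series for ind in INDICATORS)

    @property
    def missing_indicators(self) -> tuple[str, ...]:
        return tuple(ind for ind in INDICATORS if ind not in self.series)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatientRecord):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.label == other.label
            and self.series == other.series
        )


@dataclass
class CohortDataset:
    """Ordered collection of patient records with provenance."""

    records: list[PatientRecord]
    provenance: str = "file"

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def class_counts(self) -> dict[int, int]:
        labels = self.labels
        return {0: int(np.sum(labels == 0)), 1: int(np.sum(labels == 1))}

    def complete_records(self) -> list[PatientRecord]:
        """Complete records only; incomplete ones are counted and logged,
        mirroring the exclusion of patients with incomplete monitoring data."""
        complete = [r for r in self.records if r.is_complete]
        n_dropped = len(self.records) - len(complete)
        if n_dropped:
            logger.warning("excluded %d incomplete record(s)", n_dropped)
        return complete


def read_cohort(series_path, labels_path) -> CohortDataset:
    """Read a labelled cohort from the two-file CSV layout.

    Rows whose indicator is not one of :data:`INDICATORS` are rejected with a
    logged report.  A patient appearing in the series file without a label is
    a hard error; non-numeric values are a hard error naming the row.
    """
    series_df = pd.read_csv(
        series_path, dtype={"patient_id": str}, float_precision="round_trip"
    )
    labels_df = pd.read_csv(labels_path, dtype={"patient_id": str})
    for col in SERIES_COLUMNS:
        if col not in series_df.columns:
            raise ValueError(f"series file missing column {col!r}")
    for col in LABEL_COLUMNS:
        if col not in labels_df.columns:
            raise ValueError(f"labels file missing column {col!r}")

    numeric = pd.to_numeric(series_df["value"], errors="coerce")
    bad = numeric.isna() & series_df["value"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"non-numeric value {series_df['value'].iloc[row]!r} "
            f"at series row {row + 2}"  # +2: header line + 1-based
        )
    series_df["value"] = numeric

    unknown = ~series_df["indicator"].isin(INDICATORS)
    if unknown.any():
        rejected = series_df.loc[unknown, "indicator"].value_counts().to_dict()
        logger.warning("rejected rows with unknown indicator(s): %s", rejected)
        series_df = series_df.loc[~unknown]

    label_map = dict(zip(labels_df["patient_id"], labels_df["label"]))
    records = []
    for pid, group in series_df.groupby("patient_id", sort=True):
        if pid not in label_map:
            raise ValueError(f"no label for patient {pid!r}")
        series = {}
        for ind, g in group.groupby("indicator"):
            t = g["t_seconds"].to_numpy(dtype=float)
            v = g["value"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                logger.warning("unsorted times for patient %s/%s; sorting", pid, ind)
            order = np.argsort(t, kind="stable")
            series[ind] = VitalSeries(ind, t[order], v[order])
        records.append(PatientRecord(pid, int(label_map[pid]), series))
    return CohortDataset(records, provenance="file")


def write_cohort(cohort: CohortDataset, series_path, labels_path) -> None:
    """Write a cohort in the two-file CSV layout (inverse of :func:`read_cohort`)."""
    rows = []
    for rec in cohort:
        for ind in INDICATORS:
            if ind not in rec.series:
                continue
            s = rec.series[ind]
            for t, v in zip(s.times, s.values):
                rows.append((rec.patient_id, ind, t, v))
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(
        series_path, index=False, float_format="%.17g"  # exact float round-trip
    )
    pd.DataFrame(
        [(r.patient_id, r.label) for r in cohort], columns=LABEL_COLUMNS
    ).to_csv(labels_path, index=False)


def derive_pp(record: PatientRecord, replace_existing: bool = False) -> PatientRecord:
    """Add the pulse-pressure series ``pp_t = nisysbp_t - nidiasbp_t``.

    Systolic and diastolic series are aligned by exact timestamp match; the
    pp series is defined on the intersection of their time grids.  An existing
    pp series is kept unless ``replace_existing`` is set.
    """
    if "pp" in record.series and not replace_existing:
        return record
    for ind in ("nisysbp", "nidiasbp"):
        if ind not in record.series:
            raise ValueError(f"cannot derive pp: missing {ind}")
    sys_s = record.series["nisysbp"]
    dia_s = record.series["nidiasbp"]
    common, i_sys, i_dia = np.intersect1d(
        sys_s.times, dia_s.times, assume_unique=True, return_indices=True
    )
    if len(common) == 0:
        raise ValueError("nisysbp and nidiasbp share no timestamps")
    pp = VitalSeries("pp", common, sys_s.values[i_sys] - dia_s.values[i_dia])
    series = dict(record.series)
    series["pp"] = pp
    return replace(record, series=series)


def zscore_normalize(series: VitalSeries) -> VitalSeries:
    """Standardize values to mean 0, population standard deviation 1.

    Raises on constant series ("constant series cannot be z-normalized");
    the caller decides whether to skip or impute such patients.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 points to z-normalize")
    v = series.values
    mu = v.mean()
    sigma = v.std()  # population (1/N) convention, as elsewhere in the package
    if sigma == 0:
        raise ValueError("constant series cannot be z-normalized")
    # bypass the physical-range check: standardized spo2 is no longer a %
    return _raw_series(series.indicator, series.times, (v - mu) / sigma)


def _raw_series(indicator: str, times: np.ndarray, values: np.ndarray) -> VitalSeries:
    """Build a VitalSeries bypassing the physical-range check (z-scale data)."""
    s = object.__new__(VitalSeries)
    s.indicator = indicator
    s.times = np.asarray(times, dtype=float)
    s.values = np.asarray(values, dtype=float)
    return s
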