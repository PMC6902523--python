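"""Statistical derivative variables of vital-sign series and the correlation filter.

Each patient is summarized by 90 named features: for each of the five channels,
nine summary statistics (mean, std, min, 25/50/75% quantiles, max, skewness,
kurtosis) of the raw series and of its first-order difference.

Moment conventions (they matter, and differ from common library defaults):

* mean and variance use the population 1/T normalization (no Bessel correction);
* skewness and kurtosis are the standardized third and fourth moments, with
  kurtosis *not* excess (a normal sample has kurtosis ~ 3, not 0);
* quantiles locate rank (n+1)p in the sorted sample with linear interpolation
  between order statistics, so e.g. the 25% quantile of 7 points is exactly the
  value at rank (7+1)/4 = 2.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import INDICATORS, CohortDataset, PatientRecord

logger = logging.getLogger(__name__)

STAT_NAMES = ("mean", "std", "min", "perc25", "perc50", "perc75", "max", "skew", "kurt")

#: channel spellings used in feature names (diastolic is spelled with a
#: trailing 'e' in the naming convention this package follows)
_FEATURE_CHANNEL = {
    "hr": "hr",
    "nisysbp": "nisysbp",
    "nidiasbp": "nidiasbpe",
    "spo2": "spo2",
    "pp": "pp",
}


def _quantile(sorted_x: np.ndarray, p: float) -> float:
    """Rank-(n+1)p quantile with linear interpolation, rank clipped to [1, n]."""
    n = len(sorted_x)
    rank = np.clip((n + 1) * p, 1.0, float(n))
    lo = int(np.floor(rank)) - 1
    hi = int(np.ceil(rank)) - 1
    frac = rank - np.floor(rank)
    return float(sorted_x[lo] + frac * (sorted_x[hi] - sorted_x[lo]))


@dataclass
class SeriesStats:
    """The nine summary statistics of one value sequence."""

    stats: "OrderedDict[str, float]"
    degenerate: bool  # sigma == 0: skew and kurt reported as 0 by policy

    def __getitem__(self, key: str) -> float:
        return self.stats[key]


def base_stats(x) -> SeriesStats:
    """Compute the nine summary statistics of a value sequence.

    A zero-variance sequence gets skew = kurt = 0 with the ``degenerate``
    flag set, rather than NaN; empty input is an error.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute statistics of an empty sequence")
    mu = float(x.mean())
    var = float(np.mean((x - mu) ** 2))  # population 1/T
    sigma = float(np.sqrt(var))
    sx = np.sort(x)
    degenerate = sigma == 0.0
    if degenerate:
        skew = kurt = 0.0
    else:
        z = (x - mu) / sigma
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))  # non-excess: ~3 for a normal sample
    stats = OrderedDict(
        [
            ("mean", mu),
            ("std", sigma),
            ("min", float(sx[0])),
            ("perc25", _quantile(sx, 0.25)),
            ("perc50", _quantile(sx, 0.50)),
            ("perc75", _quantile(sx, 0.75)),
            ("max", float(sx[-1])),
            ("skew", skew),
            ("kurt", kurt),
        ]
    )
    return SeriesStats(stats, degenerate)


def first_difference(x) -> np.ndarray:
    """First-order difference ``out_i = x[i+1] - x[i]`` (length T-1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points to difference")
    return np.diff(x)


def feature_names() -> list[str]:
    """The 90 feature names, in canonical (channel-major) order."""
    names = []
    for ind in INDICATORS:
        ch = _FEATURE_CHANNEL[ind]
        for s in ("mean", "std", "min", "perc25", "perc50", "perc75", "max"):
            names.append(f"{s}_{ch}")
        for s in ("mean", "std", "min", "perc25", "perc50", "perc75", "max"):
            names.append(f"{s}_diff_{ch}")
        names.append(f"skew_{ch}")
        names.append(f"kurt_{ch}")
        names.append(f"diff-skew_diff_{ch}")
        names.append(f"diff-kurt_diff_{ch}")
    return names


@dataclass
class StatFeatureVector:
    """The 90 named statistical derivative variables of one patient."""

    patient_id: str
    features: "OrderedDict[str, float]"
    degenerate_channels: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, key: str) -> float:
        return self.features[key]


def extract_features(record: PatientRecord) -> StatFeatureVector:
    """Compute the 90-feature statistical representation of one patient."""
    missing = record.missing_indicators
    if missing:
        raise ValueError(f"record {record.patient_id!r} missing {missing[0]!r}")
    features: "OrderedDict[str, float]" = OrderedDict()
    degenerate = []
    for ind in INDICATORS:
        ch = _FEATURE_CHANNEL[ind]
        raw = base_stats(record.series[ind].values)
        diff = base_stats(first_difference(record.series[ind].values))
        if raw.degenerate or diff.degenerate:
            degenerate.append(ind)
        for s in ("mean", "std", "min", "perc25", "perc50", "perc75", "max"):
            features[f"{s}_{ch}"] = raw[s]
        for s in ("mean", "std", "min", "perc25", "perc50", "perc75", "max"):
            features[f"{s}_diff_{ch}"] = diff[s]
        features[f"skew_{ch}"] = raw["skew"]
        features[f"kurt_{ch}"] = raw["kurt"]
        features[f"diff-skew_diff_{ch}"] = diff["skew"]
        features[f"diff-kurt_diff_{ch}"] = diff["kurt"]
    return StatFeatureVector(record.patient_id, features, tuple(degenerate))


def feature_matrix(cohort: CohortDataset) -> pd.DataFrame:
    """Patient-by-feature matrix (rows id-ordered, 90 named columns)."""
    vectors = [extract_features(r) for r in cohort.complete_records()]
    df = pd.DataFrame(
        [v.features for v in vectors], index=[v.patient_id for v in vectors]
    )
    df.index.name = "patient_id"
    return df.sort_index()


def correlation_filter(
    matrix: pd.DataFrame, dedupe_threshold: float = 0.99
) -> tuple[pd.DataFrame, dict]:
    """Drop uninformative and near-duplicate columns by Pearson correlation.

    Removes (a) zero-variance columns, for which the correlation coefficient
    is undefined, and (b) for every pair with |r| >= ``dedupe_threshold``,
    the later column.  Returns the filtered matrix and a report of dropped
    names with reasons plus the full correlation matrix of the remaining
    columns (heat-map ready).
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    dropped: dict[str, str] = {}
    variances = matrix.var(axis=0, ddof=0)
    constant = variances[variances == 0.0].index.tolist()
    for name in constant:
        dropped[name] = "zero variance"
    kept = matrix.drop(columns=constant)
    corr = kept.corr()
    cols = list(kept.columns)
    to_drop = set()
    for i, a in enumerate(cols):
        if a in to_drop:
            continue
        for b in cols[i + 1 :]:
            if b in to_drop:
                continue
            if abs(corr.loc[a, b]) >= dedupe_threshold:
                to_drop.add(b)
                dropped[b] = f"|r| >= {dedupe_threshold} with {a}"
    kept = kept.drop(columns=sorted(to_drop))
    if dropped:
        logger.info("correlation filter dropped %d column(s)", len(dropped))
    report = {"dropped": dropped, "correlation": kept.corr()}
    return kept, report
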