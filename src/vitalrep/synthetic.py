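"""Synthetic intraoperative cohorts with a controllable heart-failure signature.

The real hospital cohort behind this problem cannot be shared, so experiments
run on simulated patients.  Each patient gets five correlated physiological
channels sampled on a regular intraoperative grid: a per-channel baseline,
stationary AR(1) noise (short-range autocorrelation, as monitors show), and a
bounded slow random-walk drift.  Patients labelled 1 ("heart-failure-like")
additionally receive a class signature scaled by an ``effect`` multiplier:

* elevated mean heart rate (+8 * effect bpm),
* inflated heart-rate variance (x (1 + effect)),
* a late linear SpO2 decline (-2 * effect % over the final third),
* a pulse-pressure widening trend (+10 * effect mmHg by the end of surgery,
  applied to the systolic channel so pp = sys - dia widens).

The signature is deliberately visible to all three downstream representations:
the mean shift to summary statistics, the trends to symbolic/text shape
features, and the changed time-value point distribution to the grid image.
``effect=0`` makes both classes draws from the identical process (null data);
the default cohort reproduces the 84:168 case-control design (252 patients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import CohortDataset, PatientRecord, VitalSeries, derive_pp

#: per-indicator (baseline mean, baseline sd) for the three simulated channels
DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "hr": (75.0, 8.0),
    "nisysbp": (120.0, 12.0),
    "nidiasbp": (70.0, 8.0),
    "spo2": (98.0, 1.0),
}


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the simulated cohort.

    Defaults mirror the case:control design of the motivating study
    (84 positive, 168 negative) and a 3-hour operation sampled once a minute.
    """

    n_pos: int = 84
    n_neg: int = 168
    duration_min: float = 180.0
    dt_s: float = 60.0
    baselines: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    ar_coeff: float = 0.8
    drift_sd: float = 0.1      # random-walk step sd, in units of the channel sd
    drift_bound: float = 2.0   # drift clipped to +- drift_bound * channel sd
    effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("n_pos and n_neg must be non-negative")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.effect < 0:
            raise ValueError("effect must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_min * 60.0 / self.dt_s))


def _ar1(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + shocks[t - 1]
    return e


def _drift(n: int, step_sd: float, bound: float, rng: np.random.Generator) -> np.ndarray:
    walk = np.cumsum(rng.normal(0.0, step_sd, size=n))
    return np.clip(walk, -bound, bound)


def simulate_patient(
    config: GeneratorConfig, label: int, rng: np.random.Generator, patient_id: str = "P0"
) -> PatientRecord:
    """Simulate one patient's five-channel record.

    All randomness comes from ``rng``; the same generator state yields a
    bitwise-identical record.  ``pp`` is derived from the simulated pressure
    channels via :func:`vitalrep.core_io.derive_pp`.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    n = config.n_samples
    times = np.arange(n, dtype=float) * config.dt_s
    frac = np.arange(n, dtype=float) / max(n - 1, 1)  # 0 .. 1 over the surgery
    eff = config.effect if label == 1 else 0.0

    series: dict[str, VitalSeries] = {}
    channels: dict[str, np.ndarray] = {}
    for ind in ("hr", "nisysbp", "nidiasbp", "spo2"):
        mu, sd = config.baselines[ind]
        noise_sd = sd
        level = np.full(n, mu)
        if ind == "hr":
            level = level + 8.0 * eff
            noise_sd = sd * np.sqrt(1.0 + eff)
        elif ind == "nisysbp":
            # pulse-pressure widening: systolic rises linearly to +10*eff by end
            level = level + 10.0 * eff * frac
        elif ind == "spo2":
            # late decline: last third of surgery drops linearly by 2*eff %
            decline = np.clip((frac - 2.0 / 3.0) * 3.0, 0.0, 1.0)
            level = level - 2.0 * eff * decline
        x = level + _ar1(n, config.ar_coeff, noise_sd, rng) + _drift(
            n, config.drift_sd * sd, config.drift_bound * sd, rng
        )
        channels[ind] = x

    # physiological constraints: spo2 is a percentage; systolic > diastolic
    channels["spo2"] = np.clip(channels["spo2"], 0.0, 100.0)
    gap = channels["nisysbp"] - channels["nidiasbp"]
    bad = gap <= 0
    while bad.any():  # resample violating diastolic points (rare at defaults)
        channels["nidiasbp"][bad] = channels["nisysbp"][bad] - np.abs(
            rng.normal(10.0, 5.0, size=int(bad.sum()))
        )
        bad = channels["nisysbp"] - channels["nidiasbp"] <= 0

    for ind in ("hr", "nisysbp", "nidiasbp", "spo2"):
        series[ind] = VitalSeries(ind, times, channels[ind])
    record = PatientRecord(patient_id, label, series)
    return derive_pp(record)


def simulate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Simulate a labelled cohort: ``n_pos`` positives then ``n_neg`` negatives.

    A single RNG stream derived from ``config.seed`` drives every patient, so
    the whole cohort is reproducible from (config, seed) alone.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    labels = [1] * config.n_pos + [0] * config.n_neg
    for i, label in enumerate(labels):
        records.append(simulate_patient(config, label, rng, patient_id=f"S{i:04d}"))
    return CohortDataset(records, provenance="synthetic")


def config_to_dict(config: GeneratorConfig) -> dict:
    """JSON-serializable form of a config, for provenance sidecars."""
    d = dict(config.__dict__)
    d["baselines"] = {k: list(v) for k, v in config.baselines.items()}
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "baselines" in d:
        d["baselines"] = {k: tuple(v) for k, v in d["baselines"].items()}
    return GeneratorConfig(**d)
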