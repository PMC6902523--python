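"""Model/Results front end over the representation pipelines.

Follows the familiar two-object pattern of statistical modelling packages:
a :class:`VitalSignsRiskModel` is built from a cohort (or a pair of
dataframes), ``fit()`` runs the chosen representation pipeline plus the
classifier benchmark, and the returned :class:`RiskModelResults` carries the
per-classifier metrics, fold-level dispersion, ROC curves and a ``summary()``
table.

Example
-------
>>> from vitalrep import GeneratorConfig, simulate_cohort
>>> from vitalrep.model import VitalSignsRiskModel
>>> cohort = simulate_cohort(GeneratorConfig(effect=2.0, seed=7))
>>> res = VitalSignsRiskModel(cohort, representation="statistical").fit(seed=7)
>>> print(res.summary())              # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import CohortDataset, read_cohort
from .evaluate import CLASSIFIER_NAMES, CVConfig, EvalReport, benchmark_all, evaluate_cnn, run_cv, split_cohort

REPRESENTATIONS = ("statistical", "text", "image", "all")


class VitalSignsRiskModel:
    """Heart-failure risk classification from intraoperative vital signs.

    Parameters
    ----------
    cohort : CohortDataset
        Labelled five-channel patient records.
    representation : str
        One of ``statistical``, ``text``, ``image`` or ``all``.
    **options
        Pipeline knobs: ``lda_topics`` (default 5), ``grid_shape`` (default
        (16, 16)), ``cnn_spec``, ``filter_features`` (default True),
        ``classifiers`` (tuple of names, default all eight).
    """

    def __init__(self, cohort: CohortDataset, representation: str = "statistical", **options):
        if representation not in REPRESENTATIONS:
            raise ValueError(f"representation must be one of {REPRESENTATIONS}")
        self.cohort = cohort
        self.representation = representation
        self.options = options

    @classmethod
    def from_dataframes(cls, series_df: pd.DataFrame, labels_df: pd.DataFrame, **kw):
        """Build from in-memory long-format series and label tables."""
        import io

        s, l = io.StringIO(), io.StringIO()
        series_df.to_csv(s, index=False)
        labels_df.to_csv(l, index=False)
        s.seek(0), l.seek(0)
        return cls(read_cohort(s, l), **kw)

    @classmethod
    def from_csv(cls, series_path, labels_path, **kw):
        return cls(read_cohort(series_path, labels_path), **kw)

    def fit(self, seed: int = 0, cv: CVConfig | None = None) -> "RiskModelResults":
        """Run the pipeline(s) and classifier benchmark; return results."""
        cv = cv or CVConfig(seed=seed)
        opts = self.options
        if self.representation == "all":
            report = benchmark_all(
                self.cohort,
                cv=cv,
                lda_topics=opts.get("lda_topics", 5),
                grid_shape=opts.get("grid_shape", (16, 16)),
                cnn_spec=opts.get("cnn_spec"),
                filter_features=opts.get("filter_features", True),
            )
            return RiskModelResults(self, report)

        records = self.cohort.complete_records()
        label_of = {r.patient_id: r.label for r in records}
        if self.representation == "statistical":
            from .statistical import correlation_filter, feature_matrix

            X = feature_matrix(self.cohort)
            if opts.get("filter_features", True):
                X, _ = correlation_filter(X)
            y = np.array([label_of[i] for i in X.index], dtype=int)
            report = run_cv(
                X.to_numpy(), y,
                classifiers=opts.get("classifiers", CLASSIFIER_NAMES),
                cv=cv, representation="statistical",
            )
        elif self.representation == "text":
            from .text import build_corpus, fit_lda, topic_matrix

            corpus = build_corpus(self.cohort)
            topics = topic_matrix(fit_lda(corpus, k=opts.get("lda_topics", 5), seed=cv.seed), corpus)
            y = np.array([label_of[i] for i in topics.index], dtype=int)
            report = run_cv(
                topics.to_numpy(), y,
                classifiers=opts.get("classifiers", CLASSIFIER_NAMES),
                cv=cv, representation="text",
            )
        else:  # image
            from .image import cohort_tensors

            m, n = opts.get("grid_shape", (16, 16))
            X_img, y, _ = cohort_tensors(self.cohort, m, n)
            report = evaluate_cnn(X_img, y, cv=cv, cnn_spec=opts.get("cnn_spec"))
        return RiskModelResults(self, report)


class RiskModelResults:
    """Fitted benchmark results with metrics, ROC curves and a summary table."""

    def __init__(self, model: VitalSignsRiskModel, report: EvalReport):
        self.model = model
        self.report = report

    @property
    def metrics(self) -> pd.DataFrame:
        """Held-out-test metrics, one row per (representation, classifier)."""
        return self.report.to_frame()

    @property
    def fold_metrics(self) -> pd.DataFrame:
        """Per-fold validation metrics inside the training portion."""
        return self.report.fold_frame()

    def best(self, representation: str | None = None) -> dict:
        """Row with the highest held-out AUC."""
        return self.report.best(representation)

    def summary(self) -> str:
        """Human-readable table of held-out metrics (and fold dispersion)."""
        df = self.metrics.copy()
        for c in ("TPR", "TNR", "F1", "ACC", "AUC"):
            df[c] = df[c].map(lambda v: f"{v:.3f}" if np.isfinite(v) else "nan")
        folds = self.fold_metrics
        lines = [
            "Perioperative heart-failure risk benchmark",
            "=" * 60,
            f"cohort: {len(self.model.cohort)} patients "
            f"({self.model.cohort.class_counts()[1]} positive / "
            f"{self.model.cohort.class_counts()[0]} negative), "
            f"provenance={self.model.cohort.provenance}",
            "held-out 20% test split metrics (threshold 0.5):",
            df.drop(columns=["split"]).to_string(index=False),
        ]
        if len(folds):
            disp = (
                folds.groupby(["representation", "classifier"])["AUC"]
                .agg(["mean", "std"])
                .round(3)
                .rename(columns={"mean": "cv_auc_mean", "std": "cv_auc_sd"})
            )
            lines += ["", "10-fold CV dispersion (validation AUC):", disp.to_string()]
        return "\n".join(lines)

    def plot_roc(self, path=None):
        """ROC curves of every benchmarked classifier (one figure)."""
        from .plotting import plot_roc

        return plot_roc(self.report, path)
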