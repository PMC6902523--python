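"""Text representation of vital-sign series: PAA, SAX, rule-engine phrases, LDA topics.

Pipeline (per patient): each channel is z-normalized, reduced by piecewise
aggregate approximation (PAA) to one mean per fixed time window, discretized
into letters by symbolic aggregate approximation (SAX) with equiprobable
Gaussian breakpoints, and every non-overlapping run of three letters is turned
into a human-readable four-field phrase

    <level> <channel> <modifier> <movement>

e.g. ``"medium hr rapidly increasing"``.  A patient's document concatenates the
phrases of all five channels in fixed order; latent Dirichlet allocation (LDA)
over the phrase vocabulary then gives each patient a k-simplex topic vector
(default k = 5) that downstream classifiers consume.

The rule engine mapping letter shapes and window statistics to the phrase
vocabulary is this package's canonical, configurable definition:

* movement from the 3-letter shape: strictly ascending -> increasing, strictly
  descending -> decreasing, all equal -> steady, middle strictly greatest ->
  peak, otherwise varying;
* level from the window mean on the z scale: < -0.43 low, > +0.43 high,
  else medium (tertile cut-points of the standard normal);
* modifier: for increasing/decreasing, |net z-change| >= 1 -> rapidly else
  slowly; for peak/varying, net change >= 0 -> upward else downward;
  steady -> slowly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.decomposition import LatentDirichletAllocation

from .core_io import INDICATORS, CohortDataset, VitalSeries, zscore_normalize

logger = logging.getLogger(__name__)

LEVELS = ("low", "medium", "high")
MODIFIERS = ("slowly", "rapidly", "upward", "downward")
MOVEMENTS = ("decreasing", "increasing", "steady", "peak", "varying")

_LEVEL_CUT = 0.43  # ~ standard-normal tertile boundary


@dataclass
class PAASeries:
    """Piecewise-aggregate reduction of one series: one mean per segment."""

    segment_means: np.ndarray
    segment_span_s: float
    indicator: str


@dataclass
class SAXConfig:
    """Alphabet for SAX discretization: ``a`` equiprobable Gaussian bins."""

    alphabet_size: int = 5

    def __post_init__(self) -> None:
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")

    @property
    def breakpoints(self) -> np.ndarray:
        a = self.alphabet_size
        return norm.ppf(np.arange(1, a) / a)

    @property
    def alphabet(self) -> str:
        return "".join(chr(ord("a") + i) for i in range(self.alphabet_size))


@dataclass
class TextDocument:
    """One patient's bag of rule-engine phrases."""

    patient_id: str
    words: list[str] = field(default_factory=list)


def paa(values, omega: int) -> np.ndarray:
    """Piecewise aggregate approximation: ``omega`` segment means.

    Segment i averages the points with (1-based) index in ((N/w)(i-1), (N/w)i].
    When omega does not divide N, boundary points are fractionally weighted
    between the adjacent segments so the size-weighted mean of the segments
    equals the mean of the input exactly.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if not 1 <= omega <= n:
        raise ValueError(f"omega must lie in [1, {n}], got {omega}")
    if n % omega == 0:
        return x.reshape(omega, n // omega).mean(axis=1)
    seg_len = n / omega
    edges = np.linspace(0.0, float(n), omega + 1)  # exact endpoints
    out = np.empty(omega)
    for i in range(omega):
        lo, hi = edges[i], edges[i + 1]
        j = np.arange(int(np.floor(lo)), min(int(np.ceil(hi)), n))
        # overlap of point j's unit interval [j, j+1) with the segment
        w = np.minimum(j + 1, hi) - np.maximum(j, lo)
        out[i] = np.sum(w * x[j]) / seg_len
    return out


def paa_series(series: VitalSeries, span_s: float) -> PAASeries:
    """Window-membership PAA on a timestamped series.

    Windows of ``span_s`` seconds from the first timestamp; each segment is
    the mean of the points falling in its window (no interpolation).  Only
    windows fully covered by the observed span count: each sample is taken to
    represent one median sampling interval, and a trailing partially-covered
    window yields no segment.  On a regular grid of N = K * (span / dt)
    samples this coincides with index-based :func:`paa`.  A series shorter
    than one window, or an empty window, is an error (the caller's skip
    policy applies).
    """
    t = series.times - series.times[0]
    dt = float(np.median(np.diff(t))) if len(t) > 1 else span_s
    n_windows = int(np.floor((t[-1] + dt) / span_s + 1e-9))
    if n_windows < 1:
        raise ValueError("series shorter than one segment span")
    keep = t < n_windows * span_s
    idx = (t[keep] // span_s).astype(int)
    counts = np.bincount(idx, minlength=n_windows)
    if np.any(counts == 0):
        raise ValueError("window with no measurements")
    sums = np.bincount(idx, weights=series.values[keep], minlength=n_windows)
    return PAASeries(sums / counts, span_s, series.indicator)


def sax(segment_means, config: SAXConfig) -> str:
    """Map PAA segment means to letters ('a' lowest).

    A value equal to a breakpoint maps to the upper symbol (left-closed bins).
    """
    v = np.asarray(segment_means, dtype=float)
    idx = np.searchsorted(config.breakpoints, v, side="right")
    return "".join(config.alphabet[i] for i in idx)


def textualize(
    window_symbols: str,
    mean_z: float,
    net_z_change: float,
    indicator: str,
    rapid_threshold: float = 1.0,
) -> str:
    """Turn a 3-letter SAX pattern plus window statistics into a phrase."""
    if len(window_symbols) != 3:
        raise ValueError("textualize expects exactly 3 symbols")
    s = [ord(c) - ord("a") for c in window_symbols]
    if any(c < 0 or c > 25 for c in s) or not window_symbols.isalpha():
        raise ValueError(f"symbols outside alphabet: {window_symbols!r}")

    if s[0] < s[1] < s[2]:
        movement = "increasing"
    elif s[0] > s[1] > s[2]:
        movement = "decreasing"
    elif s[0] == s[1] == s[2]:
        movement = "steady"
    elif s[1] > s[0] and s[1] > s[2]:
        movement = "peak"
    else:
        movement = "varying"

    if mean_z < -_LEVEL_CUT:
        level = "low"
    elif mean_z > _LEVEL_CUT:
        level = "high"
    else:
        level = "medium"

    if movement in ("increasing", "decreasing"):
        modifier = "rapidly" if abs(net_z_change) >= rapid_threshold else "slowly"
    elif movement == "steady":
        modifier = "slowly"
    else:
        modifier = "upward" if net_z_change >= 0 else "downward"

    return f"{level} {indicator} {modifier} {movement}"


def build_corpus(
    cohort: CohortDataset,
    window_min: float = 3.0,
    symbols_per_word: int = 3,
    sax_config: SAXConfig | None = None,
    per_indicator: bool = False,
) -> list[TextDocument]:
    """Textualize every complete patient of a cohort.

    Per channel: z-normalize, PAA with ``window_min``-minute segments, SAX,
    then one phrase per non-overlapping run of ``symbols_per_word`` letters.
    Documents concatenate channels in fixed order (or stay per-channel with
    ``per_indicator``, yielding 5 documents per patient).  Patients whose
    series are constant or too short for one complete phrase are skipped with
    a log entry.
    """
    sax_config = sax_config or SAXConfig()
    span_s = window_min * 60.0
    docs: list[TextDocument] = []
    for record in cohort.complete_records():
        try:
            channel_words: dict[str, list[str]] = {}
            for ind in INDICATORS:
                z = zscore_normalize(record.series[ind])
                segs = paa_series(z, span_s).segment_means
                symbols = sax(segs, sax_config)
                n_words = len(symbols) // symbols_per_word
                if n_words == 0:
                    raise ValueError("series too short for one phrase")
                words = []
                for k in range(n_words):
                    sl = slice(k * symbols_per_word, (k + 1) * symbols_per_word)
                    window = segs[sl]
                    words.append(
                        textualize(
                            symbols[sl],
                            mean_z=float(window.mean()),
                            net_z_change=float(window[-1] - window[0]),
                            indicator=ind,
                        )
                    )
                channel_words[ind] = words
        except ValueError as err:
            logger.warning("skipping patient %s: %s", record.patient_id, err)
            continue
        if per_indicator:
            for ind in INDICATORS:
                docs.append(
                    TextDocument(f"{record.patient_id}:{ind}", channel_words[ind])
                )
        else:
            merged: list[str] = []
            for ind in INDICATORS:
                merged.extend(channel_words[ind])
            docs.append(TextDocument(record.patient_id, merged))
    return docs


@dataclass
class TopicModel:
    """Fitted LDA model plus the phrase vocabulary it was trained on."""

    lda: LatentDirichletAllocation
    vocabulary: dict[str, int]
    k: int

    def doc_term(self, docs: list[TextDocument]) -> np.ndarray:
        m = np.zeros((len(docs), len(self.vocabulary)))
        for i, doc in enumerate(docs):
            for w in doc.words:
                j = self.vocabulary.get(w)
                if j is not None:
                    m[i, j] += 1
        return m


def fit_lda(
    corpus: list[TextDocument],
    k: int = 5,
    alpha: float | None = None,
    eta: float | None = None,
    seed: int = 0,
) -> TopicModel:
    """Fit a k-topic LDA on the phrase corpus (symmetric priors 1/k by default)."""
    if not corpus:
        raise ValueError("empty corpus")
    if k < 2:
        raise ValueError("k must be >= 2")
    vocab: dict[str, int] = {}
    for doc in corpus:
        for w in doc.words:
            vocab.setdefault(w, len(vocab))
    if not vocab:
        raise ValueError("empty vocabulary")
    model = TopicModel(
        LatentDirichletAllocation(
            n_components=k,
            doc_topic_prior=alpha if alpha is not None else 1.0 / k,
            topic_word_prior=eta if eta is not None else 1.0 / k,
            random_state=seed,
            max_iter=30,
        ),
        vocab,
        k,
    )
    model.lda.fit(model.doc_term(corpus))
    return model


def infer_topics(model: TopicModel, document: TextDocument) -> np.ndarray:
    """Per-document topic distribution (k weights summing to 1)."""
    theta = model.lda.transform(model.doc_term([document]))[0]
    return theta / theta.sum()


def topic_matrix(model: TopicModel, corpus: list[TextDocument]) -> pd.DataFrame:
    """Patient-by-topic matrix; each row is a point on the k-simplex."""
    theta = model.lda.transform(model.doc_term(corpus))
    theta = theta / theta.sum(axis=1, keepdims=True)
    df = pd.DataFrame(
        theta,
        index=[d.patient_id for d in corpus],
        columns=[f"topic_{i}" for i in range(model.k)],
    )
    df.index.name = "patient_id"
    return df


def write_corpus(corpus: list[TextDocument], path) -> None:
    """One line per patient: ``patient_id<TAB>phrase; phrase; ...``."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(doc.patient_id + "\t" + "; ".join(doc.words) + "\n")
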