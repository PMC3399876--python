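"""Positional and linkage features, and information-gain feature analysis.

Positional features depend only on the positions ``(j, k)`` of a sentence and
figure within their article; linkage features are computed from the article's
linkage matrix and therefore are hidden at prediction time (they matter for
the sequence models and for feature analysis, not for independent per-pair
classifiers).

The ``Distance`` feature is the difference of relative positions,
``j/n_s - k/n_f``: early sentences tend to link early figures, late sentences
late figures, so the linked-instance distribution of Distance concentrates
near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "FEATURE_NAMES",
    "InstanceFeatures",
    "distance",
    "gain_permutation_pvalue",
    "instance_features",
    "linkage_features",
    "percent_information_gain",
    "positional_features",
]

FEATURE_NAMES = [
    "Distance",
    "InitialSentence",
    "LastSentence",
    "InitialFigure",
    "LastFigure",
    "PreviousSentence",
    "PreviousFigure",
    "PreviousSentAndFig",
    "SentenceDegree",
    "FigureDegree",
    "EdgesCrossed",
]


@dataclass
class InstanceFeatures:
    """Feature values for one sentence/figure instance (1-based ``j``, ``k``).

    ``previous_sentence`` and ``previous_sent_and_fig`` are ``None`` for the
    first sentence, ``previous_figure`` and ``previous_sent_and_fig`` for the
    first figure: the neighbouring cell does not exist.  Missing values are
    explicit, never silently zero; consumers that cannot handle missing values
    apply a declared fill policy.
    """

    distance: float
    initial_sentence: int
    last_sentence: int
    initial_figure: int
    last_figure: int
    previous_sentence: int | None = None
    previous_figure: int | None = None
    previous_sent_and_fig: int | None = None
    sentence_degree: int | None = None
    figure_degree: int | None = None
    edges_crossed: int | None = None

    def as_row(self, fill: float = 0.0) -> list[float]:
        vals = [
            self.distance,
            self.initial_sentence,
            self.last_sentence,
            self.initial_figure,
            self.last_figure,
            self.previous_sentence,
            self.previous_figure,
            self.previous_sent_and_fig,
            self.sentence_degree,
            self.figure_degree,
            self.edges_crossed,
        ]
        return [fill if v is None else float(v) for v in vals]


def _check_index(j: int, k: int, n_s: int, n_f: int) -> None:
    if not (1 <= j <= n_s):
        raise ValueError(f"sentence index j={j} out of range 1..{n_s}")
    if not (1 <= k <= n_f):
        raise ValueError(f"figure index k={k} out of range 1..{n_f}")


def distance(j: int, k: int, n_s: int, n_f: int) -> float:
    """Relative-position difference ``j/n_s - k/n_f``."""
    _check_index(j, k, n_s, n_f)
    return j / n_s - k / n_f


def positional_features(j: int, k: int, n_s: int, n_f: int) -> tuple[float, int, int, int, int]:
    """(Distance, InitialSentence, LastSentence, InitialFigure, LastFigure)."""
    d = distance(j, k, n_s, n_f)
    return (d, int(j == 1), int(j == n_s), int(k == 1), int(k == n_f))


def linkage_features(
    L: np.ndarray, j: int, k: int
) -> tuple[int | None, int | None, int | None, int, int, int]:
    """Linkage features of candidate cell ``(j, k)`` given linkage matrix L.

    Returns (PreviousSentence, PreviousFigure, PrevSentAndFig, SentenceDegree,
    FigureDegree, EdgesCrossed).  The previous_* entries are ``None`` when the
    neighbouring sentence/figure does not exist.  EdgesCrossed counts links
    ``(j', k')`` with ``(j'-j)`` and ``(k'-k)`` of opposite signs — links whose
    edge would cross the edge ``(j, k)`` in the bipartite order diagram.
    """
    L = np.asarray(L)
    if L.ndim != 2 or not np.isin(L, (0, 1)).all():
        raise ValueError("L must be a 2-d binary matrix")
    n_s, n_f = L.shape
    _check_index(j, k, n_s, n_f)
    prev_sent = int(L[j - 2, k - 1]) if j > 1 else None
    prev_fig = int(L[j - 1, k - 2]) if k > 1 else None
    prev_both = int(L[j - 2, k - 2]) if (j > 1 and k > 1) else None
    sent_deg = int(L[j - 1].sum() - L[j - 1, k - 1])
    fig_deg = int(L[:, k - 1].sum() - L[j - 1, k - 1])
    upper_right = int(L[: j - 1, k:].sum())
    lower_left = int(L[j:, : k - 1].sum())
    edges_crossed = upper_right + lower_left
    return (prev_sent, prev_fig, prev_both, sent_deg, fig_deg, edges_crossed)


def instance_features(L: np.ndarray, j: int, k: int) -> InstanceFeatures:
    """All positional and linkage features for one instance."""
    n_s, n_f = np.asarray(L).shape
    d, ini_s, last_s, ini_f, last_f = positional_features(j, k, n_s, n_f)
    ps, pf, psf, sd, fd, ec = linkage_features(L, j, k)
    return InstanceFeatures(
        distance=d,
        initial_sentence=ini_s,
        last_sentence=last_s,
        initial_figure=ini_f,
        last_figure=last_f,
        previous_sentence=ps,
        previous_figure=pf,
        previous_sent_and_fig=psf,
        sentence_degree=sd,
        figure_degree=fd,
        edges_crossed=ec,
    )


def _entropy(counts: Counter) -> float:
    n = sum(counts.values())
    h = 0.0
    for c in counts.values():
        if c:
            p = c / n
            h -= p * math.log2(p)
    return h


def _bin_feature(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize a feature for information-gain computation.

    Features with at most ``n_bins`` distinct values (binary indicators,
    small integer counts) are used as-is.  Continuous features are cut into
    ``n_bins`` equal-frequency bins by rank, so the binning — and hence the
    gain — is invariant to strictly monotone transformations.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("feature values must be finite (apply a fill policy first)")
    distinct = np.unique(values)
    if distinct.size <= n_bins:
        return np.searchsorted(distinct, values)
    ranks = rankdata(values, method="average")  # ties share a rank, hence a bin
    bins = np.floor((ranks - 0.5) / values.size * n_bins).astype(int)
    return np.clip(bins, 0, n_bins - 1)


def percent_information_gain(
    feature_values, labels, n_bins: int = 10
) -> float:
    """Information gain of a (binned) feature about a binary label, as a
    percentage of the label entropy: 0% = not predictive, 100% = completely
    predictive."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature_values and labels must be equal-length 1-d arrays")
    label_counts = Counter(y.tolist())
    h_y = _entropy(label_counts)
    if h_y == 0.0:
        raise ValueError("labels are all identical; information gain is undefined")
    b = _bin_feature(x, n_bins)
    n = y.size
    h_cond = 0.0
    for bv in np.unique(b):
        mask = b == bv
        h_cond += mask.sum() / n * _entropy(Counter(y[mask].tolist()))
    gain = max(h_y - h_cond, 0.0)
    return 100.0 * gain / h_y


def gain_permutation_pvalue(
    feature_values, labels, n_perm: int = 1000, seed: int = 0, n_bins: int = 10
) -> float:
    """Permutation p-value for % information gain differing from zero.

    ``p = (r + 1) / (n_perm + 1)`` where ``r`` counts label permutations whose
    gain is at least the observed gain (add-one smoothing, so a constant
    feature — all gains tie at 0 — gives exactly p = 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(labels, dtype=int)
    observed = percent_information_gain(feature_values, y, n_bins)
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if percent_information_gain(feature_values, perm, n_bins) >= observed:
            r += 1
    return (r + 1) / (n_perm + 1)
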