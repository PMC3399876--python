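"""Binned distance model over relative sentence/figure positions.

The Distance feature ``j/n_s - k/n_f`` is discretized into ten
equal-frequency bins (boundaries at the deciles of all training distances).
Separate Laplace-smoothed bin distributions are estimated for linked and
non-linked instances, and the model scores an instance by the log-odds of
its bin.  Adding the distance log-odds to the LM log-odds gives the combined
score ``Z = S + D``, which is the correct joint log-odds under conditional
independence of terms and distances given linkage status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import Article
from .features import distance
from .lm import ScoreMatrix

logger = logging.getLogger("figlink")

__all__ = ["DistanceModel", "N_BINS", "combine_scores", "dm_score_matrix", "fit_dm"]

N_BINS = 10


@dataclass
class DistanceModel:
    """Decile bin edges plus linked / non-linked bin probabilities.

    ``bin_edges`` holds the 9 interior boundaries; bins are left-closed,
    right-open, with the outer bins unbounded (prediction-time distances
    outside the training range clamp to the end bins).
    """

    bin_edges: np.ndarray
    p_linked: np.ndarray
    p_unlinked: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.p_linked = np.asarray(self.p_linked, dtype=float)
        self.p_unlinked = np.asarray(self.p_unlinked, dtype=float)
        if self.bin_edges.size != N_BINS - 1:
            raise ValueError(f"expected {N_BINS - 1} bin edges")
        for p in (self.p_linked, self.p_unlinked):
            if p.size != N_BINS or (p <= 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("bin probabilities must be positive and sum to 1")

    def bin_of(self, d) -> np.ndarray:
        """Bin index (0..9) of distance value(s); end bins absorb extremes."""
        return np.searchsorted(self.bin_edges, np.asarray(d, dtype=float), side="right")

    def log_odds(self, d) -> np.ndarray:
        b = self.bin_of(d)
        return np.log(self.p_linked[b] / self.p_unlinked[b])

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "p_linked": self.p_linked.tolist(),
            "p_unlinked": self.p_unlinked.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistanceModel":
        return cls(
            bin_edges=np.asarray(d["bin_edges"]),
            p_linked=np.asarray(d["p_linked"]),
            p_unlinked=np.asarray(d["p_unlinked"]),
        )


def _article_distances(article: Article) -> np.ndarray:
    n_s, n_f = article.n_sentences, article.n_figures
    j = np.arange(1, n_s + 1)[:, None] / n_s
    k = np.arange(1, n_f + 1)[None, :] / n_f
    return j - k


def fit_dm(train_corpus: Sequence[Article]) -> DistanceModel:
    """Fit decile bins and Laplace-smoothed bin probabilities.

    ``p_linked[b] = (c_b^+ + 1) / (N^+ + 10)`` and likewise for non-linked,
    where ``c_b`` counts training instances of that class in bin ``b``.
    """
    dists, labels = [], []
    for a in train_corpus:
        if a.linkage is None:
            raise ValueError(f"article {a.article_id!r} lacks a linkage matrix")
        dists.append(_article_distances(a).ravel())
        labels.append(a.linkage.astype(int).ravel())
    d = np.concatenate(dists)
    y = np.concatenate(labels)
    if np.unique(d).size < N_BINS:
        raise ValueError(
            f"only {np.unique(d).size} distinct distance values; need at least "
            f"{N_BINS} (use a larger training corpus)"
        )
    edges = np.quantile(d, np.arange(1, N_BINS) / N_BINS)
    bins = np.searchsorted(edges, d, side="right")
    c_pos = np.bincount(bins[y == 1], minlength=N_BINS).astype(float)
    c_neg = np.bincount(bins[y == 0], minlength=N_BINS).astype(float)
    p_linked = (c_pos + 1.0) / (c_pos.sum() + N_BINS)
    p_unlinked = (c_neg + 1.0) / (c_neg.sum() + N_BINS)
    return DistanceModel(bin_edges=edges, p_linked=p_linked, p_unlinked=p_unlinked)


def dm_score_matrix(article: Article, model: DistanceModel) -> ScoreMatrix:
    """Distance-model log-odds matrix ``D`` for one article."""
    return ScoreMatrix(model.log_odds(_article_distances(article)), kind="D")


def combine_scores(S: ScoreMatrix, D: ScoreMatrix) -> ScoreMatrix:
    """Elementwise sum ``Z = S + D`` of language- and distance-model log-odds."""
    if S.values.shape != D.values.shape:
        raise ValueError(f"shape mismatch: {S.values.shape} vs {D.values.shape}")
    return ScoreMatrix(S.values + D.values, kind="Z")
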