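"""HMMs over article-wide linkage patterns with posterior-decoding scores.

In the sentences-in-states (SIS) construction, an article with ``n``
sentences and ``T`` figures is modelled by an ``(n+1)``-state HMM: state
``q_i`` (``i >= 1``) asserts that the figure at the current observation step
links abstract sentence ``i``, and the non-linked state ``q_0`` asserts the
figure links no sentence.  A state path therefore encodes one linkage
pattern in which every figure links 0 or 1 sentences (the CRF relaxes
this).  The figures-in-states (FIS) variant swaps the roles of sentences
and figures.

Transitions are learned once for a base structure of ``M_max + 1`` states
(the largest entity count in the training corpus) by co-occurrence counting
over consecutive steps of gold linkage matrices, with a Dirichlet(1) MAP
estimate.  Per-article models restrict (or extend) the base matrix and
renormalize.  Emissions at each step are Gaussian-calibrated language-model
scores: one Gaussian for linked-instance scores, one for non-linked, with
the step's emission vector proportional to the joint density of the step's
score column under the state's implied linkage.  Linkage scores are the
posterior state probabilities from forward--backward (posterior decoding).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .corpus import Article
from .lm import ScoreMatrix

logger = logging.getLogger("figlink")

__all__ = [
    "BaseHMM",
    "DerivedHMM",
    "GaussianEmission",
    "HMMModel",
    "build_emissions",
    "derive_hmm",
    "emission_matrix",
    "fit_emission",
    "fit_hmm",
    "map_transitions",
    "path_to_linkage",
    "posterior_decode",
    "predict_hmm",
    "transition_counts",
]

VARIANTS = ("sis", "fis")
_SIGMA_FLOOR = 1e-6


def _state_view(L: np.ndarray, variant: str) -> np.ndarray:
    """Linkage matrix with rows = state entities, columns = observation steps."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    return L.T if variant == "fis" else L


def transition_counts(train_corpus: Sequence[Article], variant: str = "sis") -> tuple[np.ndarray, np.ndarray, int]:
    """Co-occurrence transition and start counts from gold linkage matrices.

    For every pair of consecutive steps ``(k-1, k)`` the count ``C[u, v]``
    is incremented for every entity ``u`` linked at step ``k-1`` and every
    ``v`` linked at step ``k``; a step with no links contributes the
    non-linked state 0.  Start counts tally the entities linked at step 1.
    Returns ``(C, start_counts, M_max)``.
    """
    Ls = []
    for a in train_corpus:
        if a.linkage is None:
            raise ValueError(f"article {a.article_id!r} lacks a linkage matrix")
        Ls.append(_state_view(a.linkage, variant))
    if not Ls:
        raise ValueError("training corpus is empty")
    m_max = max(L.shape[0] for L in Ls)
    C = np.zeros((m_max + 1, m_max + 1), dtype=float)
    start = np.zeros(m_max + 1, dtype=float)
    for L in Ls:
        cols = [np.flatnonzero(L[:, k]) + 1 for k in range(L.shape[1])]
        cols = [c if c.size else np.array([0]) for c in cols]
        for u in cols[0]:
            start[u] += 1
        for k in range(1, len(cols)):
            for u in cols[k - 1]:
                for v in cols[k]:
                    C[u, v] += 1
    return C, start, m_max


def map_transitions(C: np.ndarray) -> np.ndarray:
    """Dirichlet(1) MAP transition matrix: ``A[u,v] = (C[u,v]+1) / (row+size)``."""
    C = np.asarray(C, dtype=float)
    if (C < 0).any():
        raise ValueError("counts must be non-negative")
    size = C.shape[1]
    return (C + 1.0) / (C.sum(axis=1, keepdims=True) + size)


@dataclass
class BaseHMM:
    """Base transition structure shared by all articles of a corpus."""

    variant: str
    M_max: int
    counts: np.ndarray
    A: np.ndarray
    start_counts: np.ndarray
    start: np.ndarray

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "M_max": self.M_max,
            "counts": self.counts.tolist(),
            "A": self.A.tolist(),
            "start_counts": self.start_counts.tolist(),
            "start": self.start.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BaseHMM":
        return cls(
            variant=d["variant"],
            M_max=int(d["M_max"]),
            counts=np.asarray(d["counts"], dtype=float),
            A=np.asarray(d["A"], dtype=float),
            start_counts=np.asarray(d["start_counts"], dtype=float),
            start=np.asarray(d["start"], dtype=float),
        )


def fit_base_hmm(train_corpus: Sequence[Article], variant: str = "sis") -> BaseHMM:
    C, start_counts, m_max = transition_counts(train_corpus, variant)
    A = map_transitions(C)
    start = (start_counts + 1.0) / (start_counts.sum() + m_max + 1)
    return BaseHMM(variant=variant, M_max=m_max, counts=C, A=A,
                   start_counts=start_counts, start=start)


@dataclass
class GaussianEmission:
    """Moments of instance scores by gold linkage status."""

    mu_linked: float
    sigma_linked: float
    mu_unlinked: float
    sigma_unlinked: float

    def log_ratio(self, z) -> np.ndarray:
        """log pdf_linked(z) - log pdf_unlinked(z)."""
        z = np.asarray(z, dtype=float)
        return norm.logpdf(z, self.mu_linked, self.sigma_linked) - norm.logpdf(
            z, self.mu_unlinked, self.sigma_unlinked
        )

    def to_dict(self) -> dict:
        return {
            "mu_linked": self.mu_linked,
            "sigma_linked": self.sigma_linked,
            "mu_unlinked": self.mu_unlinked,
            "sigma_unlinked": self.sigma_unlinked,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GaussianEmission":
        return cls(**{k: float(d[k]) for k in
                      ("mu_linked", "sigma_linked", "mu_unlinked", "sigma_unlinked")})


def fit_emission(scores, labels) -> GaussianEmission:
    """Sample mean and (unbiased) standard deviation of scores per class.

    A degenerate class standard deviation is floored at a small epsilon with
    a warning.
    """
    z = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if z.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    out = []
    for cls_val in (1, 0):
        vals = z[y == cls_val]
        if vals.size < 2:
            raise ValueError(f"need at least 2 instances of class {cls_val}")
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd < _SIGMA_FLOOR:
            warnings.warn(
                f"degenerate score variance for class {cls_val}; flooring sigma at "
                f"{_SIGMA_FLOOR}", stacklevel=2,
            )
            sd = _SIGMA_FLOOR
        out.extend([mu, sd])
    return GaussianEmission(*out)


def emission_matrix(score_column, emission: GaussianEmission) -> np.ndarray:
    """Emission probabilities ``b_i(k)`` over states 0..n for one step.

    ``b_i`` for ``i >= 1`` is proportional to the joint density of the score
    column when only entity ``i`` is linked, and ``b_0`` when none is; the
    common all-unlinked factor cancels, so ``b_i / b_0`` is the linked /
    unlinked density ratio at ``z_i``.  Computed in log space, normalized to
    sum to 1.
    """
    z = np.asarray(score_column, dtype=float).ravel()
    logits = np.concatenate([[0.0], emission.log_ratio(z)])
    logits -= logits.max()
    b = np.exp(logits)
    return b / b.sum()


def build_emissions(scores: np.ndarray, emission: GaussianEmission) -> np.ndarray:
    """Emission matrix B, shape ``(n+1, T)``: column ``k`` is ``b_.(k)``."""
    scores = np.asarray(scores, dtype=float)
    return np.column_stack([emission_matrix(scores[:, k], emission)
                            for k in range(scores.shape[1])])


@dataclass
class DerivedHMM:
    """Per-article HMM: restricted transitions, start distribution, emissions."""

    A: np.ndarray
    start: np.ndarray
    B: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.n = self.A.shape[0] - 1
        if self.A.shape[0] != self.A.shape[1] or self.B.shape[0] != self.A.shape[0]:
            raise ValueError("inconsistent derived-HMM shapes")
        if not np.allclose(self.A.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")


def _restrict(vec_or_mat: np.ndarray, n: int, m_max: int) -> np.ndarray:
    """Restrict a base distribution to states 0..n, or extend it with the
    Dirichlet-prior probability mass for unseen states, then renormalize."""
    x = np.asarray(vec_or_mat, dtype=float)
    if n <= m_max:
        sub = x[: n + 1, : n + 1] if x.ndim == 2 else x[: n + 1]
    else:
        prior = 1.0 / (m_max + 1)
        if x.ndim == 2:
            sub = np.full((n + 1, n + 1), prior)
            sub[: m_max + 1, : m_max + 1] = x
        else:
            sub = np.full(n + 1, prior)
            sub[: m_max + 1] = x
    if sub.ndim == 2:
        return sub / sub.sum(axis=1, keepdims=True)
    return sub / sub.sum()


def derive_hmm(
    base: BaseHMM,
    n: int,
    emissions: np.ndarray,
    start_mode: str = "learned",
) -> DerivedHMM:
    """Per-article HMM with states ``q_0 .. q_n`` and emission matrix B.

    Transition rows of the base structure are restricted to the article's
    states and renormalized; articles larger than any training article get
    extra states carrying the prior probability mass.  The start
    distribution is either the learned first-step occupancy (Dirichlet-1
    MAP) or uniform.
    """
    if n < 1:
        raise ValueError("article must have at least one state entity")
    A = _restrict(base.A, n, base.M_max)
    if start_mode == "learned":
        start = _restrict(base.start, n, base.M_max)
    elif start_mode == "uniform":
        start = np.full(n + 1, 1.0 / (n + 1))
    else:
        raise ValueError(f"unknown start_mode {start_mode!r}")
    B = np.asarray(emissions, dtype=float)
    if B.shape[0] != n + 1:
        raise ValueError(f"emission matrix has {B.shape[0]} state rows, expected {n + 1}")
    return DerivedHMM(A=A, start=start, B=B)


def posterior_decode(hmm: DerivedHMM) -> tuple[ScoreMatrix, np.ndarray]:
    """Forward--backward posterior state probabilities.

    Returns the linkage score matrix ``H`` (rows are entity states 1..n,
    the non-linked row 0 is dropped) and the full ``(n+1, T)`` posterior
    whose columns each sum to 1.  Scaled recursions; no underflow for
    sequences of practical length.
    """
    A, start, B = hmm.A, hmm.start, hmm.B
    n_states, T = B.shape
    alpha = np.zeros((T, n_states))
    scale = np.zeros(T)
    a = start * B[:, 0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[:, t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.ones((T, n_states))
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[:, t + 1] * beta[t + 1])) / scale[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    full = post.T  # (n+1, T)
    return ScoreMatrix(full[1:], kind="H"), full


def path_to_linkage(path: Sequence[int], n: int) -> np.ndarray:
    """Linkage matrix asserted by a state path (0 = non-linked state)."""
    T = len(path)
    L = np.zeros((n, T), dtype=np.int8)
    for k, s in enumerate(path):
        if s < 0 or s > n:
            raise ValueError(f"state {s} out of range 0..{n}")
        if s > 0:
            L[s - 1, k] = 1
    return L


# ---------------------------------------------------------------------------
# End-to-end model
# ---------------------------------------------------------------------------

@dataclass
class HMMModel:
    """Trained HMM linker: base transitions + Gaussian score calibration."""

    base: BaseHMM
    emission: GaussianEmission
    start_mode: str = "learned"

    @property
    def variant(self) -> str:
        return self.base.variant

    def to_dict(self) -> dict:
        return {
            "base": self.base.to_dict(),
            "emission": self.emission.to_dict(),
            "start_mode": self.start_mode,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HMMModel":
        return cls(
            base=BaseHMM.from_dict(d["base"]),
            emission=GaussianEmission.from_dict(d["emission"]),
            start_mode=d.get("start_mode", "learned"),
        )


def fit_hmm(
    train_corpus: Sequence[Article],
    train_scores: Sequence[ScoreMatrix],
    variant: str = "sis",
    start_mode: str = "learned",
) -> HMMModel:
    """Fit base transitions from gold linkages and the Gaussian emission
    calibration from training-corpus instance scores (LM or LM+DM)."""
    base = fit_base_hmm(train_corpus, variant)
    z = np.concatenate([s.values.ravel() for s in train_scores])
    y = np.concatenate([a.linkage.astype(int).ravel() for a in train_corpus])
    emission = fit_emission(z, y)
    return HMMModel(base=base, emission=emission, start_mode=start_mode)


def predict_hmm(model: HMMModel, scores: ScoreMatrix) -> ScoreMatrix:
    """Posterior-decoding linkage scores for one article, ``n_s x n_f``."""
    z = scores.values if model.variant == "sis" else scores.values.T
    n = z.shape[0]
    B = build_emissions(z, model.emission)
    hmm = derive_hmm(model.base, n, B, model.start_mode)
    H, _ = posterior_decode(hmm)
    values = H.values if model.variant == "sis" else H.values.T
    return ScoreMatrix(values, kind="H")
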