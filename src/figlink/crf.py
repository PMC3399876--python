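"""Linear-chain CRF over sentence-subset states for collective linkage.

The sentences-in-states (SIS) CRF generalizes the SIS HMM in two ways.
First, a state is any *subset* of the article's sentences with at most
``D_max`` members (default 2), so a single path can link one figure to
several sentences; the empty set is the non-linked state.  Second, the
affinity of a transition is not a learned per-pair probability but
``exp(w . f(s -> s'))`` for a shared vector of eight transition features,
so regularities such as "crossing edges are rare" generalize across
states.  The probability of a state path is proportional to the product of
its start affinity, its per-step emission affinities (Gaussian-calibrated
LM scores, exactly as in the HMM) and its transition affinities.

Features (evaluated on source subset ``A`` and destination subset ``A'``):
a one-hot group on the destination degree ``|A'|`` (0 / 1 / 2 / 3-or-more),
the number of crossed edges implied by the transition, and three
neighbourhood-pattern counts: ``|A ∩ A'|`` (a sentence linked by both
figures), ``|{i in A' : i-1 in A'}|`` (adjacent sentences linked by the
same figure; counted on the destination only, to avoid double counting)
and ``|{i in A' : i-1 in A}|`` (diagonal neighbour pattern).  Under the
figures-in-states (FIS) variant the roles of sentences and figures swap
and the degree one-hot becomes a sentence-degree group.

Weights are trained by batch gradient ascent on the conditional
log-likelihood of the gold state paths (with optional L2 regularization);
prediction computes per-step state posteriors with forward--backward, and
the linkage score of ``(i, k)`` is the posterior mass of states containing
``i`` at step ``k``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import Article
from .hmm import GaussianEmission, fit_emission
from .lm import ScoreMatrix

logger = logging.getLogger("figlink")

__all__ = [
    "CRF_FEATURE_NAMES",
    "CRFModel",
    "emission_affinities",
    "enumerate_states",
    "path_unnormalized_prob",
    "predict_crf",
    "start_features",
    "train_crf",
    "transition_features",
]

# Under FIS, "FigureDegree" reads as sentence degree and the sentence/figure
# roles in the neighbourhood features swap; the structure is identical.
CRF_FEATURE_NAMES = (
    "FigureDegree0",
    "FigureDegree1",
    "FigureDegree2",
    "FigureDegree3plus",
    "EdgesCrossed",
    "PreviousFigure",
    "PreviousSentence",
    "PrevSentAndFig",
)
N_FEATURES = len(CRF_FEATURE_NAMES)


def _lse(x: np.ndarray, axis: int | None = None):
    """Plain log-sum-exp (hot path: called once per chain step)."""
    m = np.max(x, axis=axis, keepdims=axis is not None)
    out = np.log(np.sum(np.exp(x - m), axis=axis)) + np.squeeze(m, axis=axis) if axis is not None else np.log(np.sum(np.exp(x - m))) + m
    return out


def enumerate_states(n: int, d_max: int) -> list[tuple[int, ...]]:
    """All subsets of entities {1..n} with size <= d_max, by size then
    lexicographically; the empty tuple (non-linked state) comes first."""
    if n < 1 or d_max < 1:
        raise ValueError("n and d_max must be >= 1")
    states: list[tuple[int, ...]] = []
    for size in range(min(d_max, n) + 1):
        states.extend(itertools.combinations(range(1, n + 1), size))
    return states


def transition_features(source: Sequence[int], dest: Sequence[int]) -> np.ndarray:
    """Length-8 feature vector for the transition ``source -> dest``."""
    A, Ap = frozenset(source), frozenset(dest)
    f = np.zeros(N_FEATURES)
    deg = min(len(Ap), 3)
    f[deg] = 1.0
    f[4] = sum(1 for i in Ap for ip in A if ip > i)  # crossed edges
    f[5] = len(A & Ap)  # PreviousFigure
    f[6] = sum(1 for i in Ap if i - 1 in Ap)  # PreviousSentence (dest only)
    f[7] = sum(1 for i in Ap if i - 1 in A)  # PrevSentAndFig
    return f


def start_features(dest: Sequence[int]) -> np.ndarray:
    """Features for starting in ``dest``: a transition from the empty set."""
    return transition_features((), dest)


class _StateSpace:
    """Cached state enumeration and feature tensors for one (n, d_max)."""

    def __init__(self, n: int, d_max: int):
        self.n = n
        self.d_max = d_max
        self.states = enumerate_states(n, d_max)
        self.index = {s: i for i, s in enumerate(self.states)}
        S = len(self.states)
        self.F = np.zeros((S, S, N_FEATURES))
        for a, sa in enumerate(self.states):
            for b, sb in enumerate(self.states):
                self.F[a, b] = transition_features(sa, sb)
        self.F2 = self.F.reshape(S * S, N_FEATURES)
        self.F_start = np.vstack([start_features(s) for s in self.states])
        # membership[s, i-1] = 1 if entity i is in state s
        self.membership = np.zeros((S, n))
        for a, sa in enumerate(self.states):
            for i in sa:
                self.membership[a, i - 1] = 1.0

    @property
    def n_states(self) -> int:
        return len(self.states)


_SPACE_CACHE: dict[tuple[int, int], _StateSpace] = {}


def _space(n: int, d_max: int) -> _StateSpace:
    key = (n, d_max)
    if key not in _SPACE_CACHE:
        _SPACE_CACHE[key] = _StateSpace(n, d_max)
    return _SPACE_CACHE[key]


def emission_affinities(
    scores: np.ndarray, emission: GaussianEmission, states: Sequence[tuple[int, ...]]
) -> np.ndarray:
    """Emission affinity matrix E, shape ``(n_states, T)``, columns sum to 1.

    ``E[s, k]`` is proportional to the joint Gaussian density of the step's
    score column when exactly the entities of state ``s`` are linked; the
    all-unlinked factor is common to every state and cancels under the
    normalization, leaving the product of per-entity density ratios.
    """
    z = np.asarray(scores, dtype=float)
    lr = emission.log_ratio(z)  # (n, T)
    S, T = len(states), z.shape[1]
    logE = np.zeros((S, T))
    for si, st in enumerate(states):
        if st:
            idx = np.array(st) - 1
            logE[si] = lr[idx].sum(axis=0)
    logE -= _lse(logE, axis=0)[None, :]
    return np.exp(logE)


def path_unnormalized_prob(
    path: Sequence[Sequence[int]],
    w: np.ndarray,
    E: np.ndarray,
    states: Sequence[tuple[int, ...]],
) -> float:
    """Unnormalized probability of a state path: the product of its start,
    emission and transition affinities.  Computed in log space."""
    index = {tuple(s): i for i, s in enumerate(states)}
    ids = [index[tuple(s)] for s in path]
    if len(ids) != E.shape[1]:
        raise ValueError("path length must equal the number of observation steps")
    log_p = float(start_features(path[0]) @ w) + np.log(E[ids[0], 0])
    for k in range(1, len(ids)):
        log_p += float(transition_features(path[k - 1], path[k]) @ w)
        log_p += np.log(E[ids[k], k])
    return float(np.exp(log_p))


def _forward_backward(
    logT: np.ndarray, log_start: np.ndarray, logE: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Log-domain forward/backward messages and the log partition function."""
    S, T = logE.shape
    alpha = np.zeros((T, S))
    alpha[0] = log_start + logE[:, 0]
    for t in range(1, T):
        alpha[t] = _lse(alpha[t - 1][:, None] + logT, axis=0) + logE[:, t]
    beta = np.zeros((T, S))
    for t in range(T - 2, -1, -1):
        beta[t] = _lse(logT + (logE[:, t + 1] + beta[t + 1])[None, :], axis=1)
    return alpha, beta, float(_lse(alpha[-1]))


def _gold_path(L: np.ndarray, d_max: int) -> tuple[list[tuple[int, ...]], int]:
    """Gold state path from a linkage matrix (rows = entities, cols = steps).

    A step linking more than ``d_max`` entities keeps the ``d_max``
    lowest-indexed ones; the number of truncated steps is returned.
    """
    path, truncated = [], 0
    for k in range(L.shape[1]):
        linked = tuple((np.flatnonzero(L[:, k]) + 1).tolist())
        if len(linked) > d_max:
            truncated += 1
            linked = linked[:d_max]
        path.append(linked)
    return path, truncated


@dataclass
class CRFModel:
    """Trained CRF: feature weights, state-size cap and score calibration."""

    weights: np.ndarray
    d_max: int
    variant: str
    emission: GaussianEmission
    training: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "weights": dict(zip(CRF_FEATURE_NAMES, self.weights.tolist())),
            "d_max": self.d_max,
            "variant": self.variant,
            "emission": self.emission.to_dict(),
            "training": self.training,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CRFModel":
        return cls(
            weights=np.array([d["weights"][name] for name in CRF_FEATURE_NAMES]),
            d_max=int(d["d_max"]),
            variant=d["variant"],
            emission=GaussianEmission.from_dict(d["emission"]),
            training=dict(d.get("training", {})),
        )


def _article_terms(
    article: Article, scores: ScoreMatrix, variant: str, d_max: int,
    emission: GaussianEmission,
):
    z = scores.values if variant == "sis" else scores.values.T
    n = z.shape[0]
    space = _space(n, d_max)
    E = emission_affinities(z, emission, space.states)
    logE = np.log(E)
    L = article.linkage if variant == "sis" else article.linkage.T
    path, truncated = _gold_path(L, d_max)
    ids = np.array([space.index[s] for s in path])
    f_obs = start_features(path[0]).copy()
    for k in range(1, len(path)):
        f_obs += transition_features(path[k - 1], path[k])
    return space, logE, ids, f_obs, truncated


def objective_only(w: np.ndarray, prepared: Sequence[tuple], l2: float) -> float:
    """Regularized conditional log-likelihood (forward pass only; used by
    the line search, which does not need gradients at rejected points)."""
    obj = -0.5 * l2 * float(w @ w)
    for space, logE, ids, _f_obs, _ in prepared:
        logT = space.F @ w
        log_start = space.F_start @ w
        S, T = logE.shape
        alpha = log_start + logE[:, 0]
        for t in range(1, T):
            alpha = _lse(alpha[:, None] + logT, axis=0) + logE[:, t]
        logZ = float(_lse(alpha))
        ll = float(log_start[ids[0]]) + float(logE[ids[0], 0])
        for k in range(1, T):
            ll += float(logT[ids[k - 1], ids[k]]) + float(logE[ids[k], k])
        obj += ll - logZ
    if not np.isfinite(obj):
        raise FloatingPointError(f"non-finite CRF objective at weights {w}")
    return obj


def objective_and_gradient(
    w: np.ndarray,
    prepared: Sequence[tuple],
    l2: float,
) -> tuple[float, np.ndarray]:
    """Regularized conditional log-likelihood of the gold paths and its
    analytic gradient (observed minus expected feature counts)."""
    obj = -0.5 * l2 * float(w @ w)
    grad = -l2 * w.copy()
    for space, logE, ids, f_obs, _ in prepared:
        logT = space.F @ w
        log_start = space.F_start @ w
        alpha, beta, logZ = _forward_backward(logT, log_start, logE)
        T = logE.shape[1]
        ll = float(log_start[ids[0]]) + float(logE[ids[0], 0])
        for k in range(1, T):
            ll += float(logT[ids[k - 1], ids[k]]) + float(logE[ids[k], k])
        obj += ll - logZ
        grad += f_obs
        gamma0 = np.exp(alpha[0] + beta[0] - logZ)
        grad -= space.F_start.T @ gamma0
        for k in range(1, T):
            log_xi = (
                alpha[k - 1][:, None] + logT + (logE[:, k] + beta[k])[None, :] - logZ
            )
            grad -= space.F2.T @ np.exp(log_xi).ravel()
    if not np.isfinite(obj):
        raise FloatingPointError(f"non-finite CRF objective at weights {w}")
    return obj, grad


def train_crf(
    train_corpus: Sequence[Article],
    train_scores: Sequence[ScoreMatrix],
    variant: str = "sis",
    d_max: int = 2,
    l2: float = 1e-2,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
    jitter: float = 0.0,
) -> CRFModel:
    """Train transition-feature weights by batch gradient ascent.

    Deterministic: weights start at zero (optionally jittered with the
    seeded generator), steps use backtracking line search on the
    regularized log-likelihood, and iteration stops when the gradient
    infinity-norm falls below ``tol`` or after ``max_iter`` iterations.
    The Gaussian emission calibration is fitted from the training scores
    and gold labels, exactly as for the HMM.
    """
    if variant not in ("sis", "fis"):
        raise ValueError(f"unknown variant {variant!r}")
    z = np.concatenate([s.values.ravel() for s in train_scores])
    y = np.concatenate([a.linkage.astype(int).ravel() for a in train_corpus])
    emission = fit_emission(z, y)

    prepared = [
        _article_terms(a, s, variant, d_max, emission)
        for a, s in zip(train_corpus, train_scores)
    ]
    n_truncated = sum(p[4] for p in prepared)
    if n_truncated:
        logger.info("gold paths truncated to d_max=%d at %d steps", d_max, n_truncated)

    w = np.zeros(N_FEATURES)
    if jitter > 0.0:
        w += np.random.default_rng(seed).normal(0.0, jitter, N_FEATURES)
    obj, grad = objective_and_gradient(w, prepared, l2)
    step = 1.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.abs(grad).max() < tol:
            break
        step = min(step * 2.0, 64.0)
        gnorm2 = float(grad @ grad)
        while True:
            w_new = w + step * grad
            obj_new = objective_only(w_new, prepared, l2)
            if obj_new >= obj + 1e-4 * step * gnorm2 or step < 1e-12:
                break
            step *= 0.5
        if step < 1e-12:
            break
        w, obj = w_new, obj_new
        _, grad = objective_and_gradient(w, prepared, l2)
    converged = bool(np.abs(grad).max() < tol)
    logger.info(
        "train_crf(%s, d_max=%d): %d iterations, objective %.4f, converged=%s",
        variant, d_max, n_iter, obj, converged,
    )
    return CRFModel(
        weights=w,
        d_max=d_max,
        variant=variant,
        emission=emission,
        training={
            "iterations": n_iter,
            "objective": obj,
            "converged": converged,
            "l2": l2,
            "truncated_steps": n_truncated,
        },
    )


def predict_crf(model: CRFModel, scores: ScoreMatrix) -> ScoreMatrix:
    """Posterior linkage scores for one article.

    Computes per-step posteriors over subset states with forward--backward;
    the score of instance ``(i, k)`` is the total posterior probability of
    states containing entity ``i`` at step ``k``, a value in [0, 1].
    """
    z = scores.values if model.variant == "sis" else scores.values.T
    n = z.shape[0]
    space = _space(n, model.d_max)
    E = emission_affinities(z, model.emission, space.states)
    logT = space.F @ model.weights
    log_start = space.F_start @ model.weights
    alpha, beta, logZ = _forward_backward(logT, log_start, np.log(E))
    gamma = np.exp(alpha + beta - logZ)  # (T, S), rows sum to 1
    values = (gamma @ space.membership).T  # (n, T)
    if model.variant == "fis":
        values = values.T
    return ScoreMatrix(values, kind="CRF")
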