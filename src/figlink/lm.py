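"""Query-likelihood language models scoring sentence/figure textual coherence.

The model treats an abstract sentence as a "query" and a figure as a
"document".  If sentence ``x`` links figure ``k``, its terms are generated by
a two-component mixture: with probability ``lambda`` from an article-wide
background distribution ``P_B`` and with probability ``1 - lambda`` from the
figure-specific distribution ``P_k``; if they are not linked, all terms come
from the background.  The per-instance score is the log-odds of the sentence
terms under these two hypotheses,

    S[j, k] = sum_{t in sentence j} log( (lambda*P_B(t) + (1-lambda)*P_k(t))
                                         / P_B(t) ),

summed over the sentence's *distinct* terms (sentences are sets of words).

Figure-specific distributions come in four flavours — caption terms only,
referencing-paragraph terms only, the pooled combination, or a ``beta``-
weighted mixture of the caption and referencing distributions.  Background
distributions come in two flavours: VariableSize (add-one smoothing over the
article's own distinct-term pool) and FixedSize (add-one smoothing with a
corpus-level fixed vocabulary size ``V``, which removes a length bias that
VariableSize has against long sentences).  The (FixedSize, Mixture) pairing
is the CompleteLM.

Mixing proportions and ``V`` are supervised: ``lambda`` (and ``beta``)
maximize the mean per-article maximum-F1 on training articles over fixed
grids, and ``V`` minimizes the absolute Pearson correlation between sentence
length and score.  A TFIDF-cosine similarity is included as the comparison
baseline.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import (
    Article,
    DEFAULT_TOKENIZER,
    TermVector,
    TokenizerConfig,
    figure_counts,
    sentence_vector,
    tokenize,
)

logger = logging.getLogger("figlink")

__all__ = [
    "FIGURE_MODELS",
    "BACKGROUND_MODELS",
    "BackgroundModel",
    "LMConfig",
    "ScoreMatrix",
    "background_prob",
    "figure_term_prob",
    "fit_lm",
    "lambda_grid",
    "lm_score",
    "max_f1",
    "score_article",
    "simplex_grid",
    "tfidf_baseline_score",
]

FIGURE_MODELS = ("caption_only", "referencing_only", "pooled", "mixture")
BACKGROUND_MODELS = ("variable_size", "fixed_size")

# Numerical floor for the per-term odds ratio; only reachable at the
# degenerate search-boundary lambda = 0 with a zero figure probability.
_RATIO_FLOOR = 1e-12


@dataclass
class ScoreMatrix:
    """Per-article ``n_s x n_f`` real matrix of linkage scores.

    ``kind`` labels the producing model: "S" (LM log-odds), "D" (distance
    model log-odds), "Z" (combined LM+DM), "H" (HMM posteriors), "CRF"
    (CRF posteriors) or "TFIDF" (baseline cosine).
    """

    values: np.ndarray
    kind: str = "S"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ScoreMatrix values must be 2-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("ScoreMatrix entries must be finite")


@dataclass
class LMConfig:
    """Language-model configuration and learned parameters.

    ``lam`` is the background mixing proportion, ``beta`` the caption mixing
    proportion (mixture figure models only) and ``V`` the fixed vocabulary
    size (fixed-size backgrounds only).  ``diagnostics`` records the search
    grids and objective values from fitting.
    """

    figure_model: str = "mixture"
    background_model: str = "fixed_size"
    lam: float | None = None
    beta: float | None = None
    V: int | None = None
    tokenizer: TokenizerConfig = field(default_factory=TokenizerConfig)
    diagnostics: dict = field(default_factory=dict, repr=False)

    def validate(self) -> None:
        if self.figure_model not in FIGURE_MODELS:
            raise ValueError(f"unknown figure_model {self.figure_model!r}")
        if self.background_model not in BACKGROUND_MODELS:
            raise ValueError(f"unknown background_model {self.background_model!r}")
        if self.lam is not None and not (0.0 <= self.lam <= 1.0):
            raise ValueError("lam must lie in [0, 1]")
        if (self.beta is not None) != (self.figure_model == "mixture"):
            raise ValueError("beta must be set iff figure_model == 'mixture'")
        if (self.V is not None) != (self.background_model == "fixed_size"):
            raise ValueError("V must be set iff background_model == 'fixed_size'")

    def to_dict(self) -> dict:
        return {
            "figure_model": self.figure_model,
            "background_model": self.background_model,
            "lambda": self.lam,
            "beta": self.beta,
            "V": self.V,
            "tokenizer": self.tokenizer.to_dict(),
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LMConfig":
        return cls(
            figure_model=d["figure_model"],
            background_model=d["background_model"],
            lam=d.get("lambda"),
            beta=d.get("beta"),
            V=d.get("V"),
            tokenizer=TokenizerConfig.from_dict(d.get("tokenizer", {})),
            diagnostics=dict(d.get("diagnostics", {})),
        )


# ---------------------------------------------------------------------------
# Elementary distributions (reference semantics, dict-based)
# ---------------------------------------------------------------------------

def _freq_dist(tv: TermVector) -> dict[str, float]:
    if tv.total == 0:
        return {}
    return {t: c / tv.total for t, c in tv.entries.items()}


def figure_term_prob(
    caption: TermVector,
    referencing: TermVector,
    figure_model: str,
    beta: float | None = None,
) -> dict[str, float]:
    """Figure-specific term distribution ``P_k``.

    Raw frequencies per source; no pseudo-counts (terms absent from the
    figure's text are covered by the background distribution).  If the chosen
    source is empty the other source is used instead (logged); if both are
    empty the distribution is empty and all mass falls to the background.
    """
    if figure_model not in FIGURE_MODELS:
        raise ValueError(f"unknown figure_model {figure_model!r}")
    cap_empty, ref_empty = caption.total == 0, referencing.total == 0
    if figure_model == "pooled":
        pooled = dict(caption.entries)
        for t, c in referencing.entries.items():
            pooled[t] = pooled.get(t, 0) + c
        return _freq_dist(TermVector(pooled))
    # effective caption / referencing distributions with empty-source fallback
    p_cap = _freq_dist(referencing if cap_empty else caption)
    p_ref = _freq_dist(caption if ref_empty else referencing)
    if cap_empty and not ref_empty and figure_model in ("caption_only", "mixture"):
        logger.debug("empty caption: falling back to referencing text")
    if ref_empty and not cap_empty and figure_model in ("referencing_only", "mixture"):
        logger.debug("empty referencing text: falling back to caption")
    if figure_model == "caption_only":
        return p_cap
    if figure_model == "referencing_only":
        return p_ref
    if beta is None:
        raise ValueError("mixture figure model requires beta")
    out = {t: beta * p for t, p in p_cap.items()}
    for t, p in p_ref.items():
        out[t] = out.get(t, 0.0) + (1.0 - beta) * p
    return {t: p for t, p in out.items() if p > 0.0}


@dataclass
class BackgroundModel:
    """Article background distribution with an explicit unseen-term default."""

    probs: dict[str, float]
    unseen: float
    N: int
    V_d: int

    def prob(self, term: str) -> float:
        return self.probs.get(term, self.unseen)


def background_prob(
    article: Article,
    background_model: str = "variable_size",
    V: int | None = None,
    tokenizer: TokenizerConfig = DEFAULT_TOKENIZER,
) -> BackgroundModel:
    """Background distribution over the article's pooled text.

    The pool is every token of every abstract sentence, caption and
    referencing paragraph.  VariableSize: add-one smoothing over the pool's
    own ``V_d`` distinct terms, unseen terms have probability zero.
    FixedSize: add-one smoothing with vocabulary size ``V``; any unseen term
    has probability ``1 / (N + V)``.
    """
    if background_model not in BACKGROUND_MODELS:
        raise ValueError(f"unknown background_model {background_model!r}")
    counts: dict[str, int] = {}
    for s in article.sentences:
        for t in tokenize(s, tokenizer):
            counts[t] = counts.get(t, 0) + 1
    for f in article.figures:
        for text in [f.caption_text, *f.referencing_paragraphs]:
            for t in tokenize(text, tokenizer):
                counts[t] = counts.get(t, 0) + 1
    if not counts:
        raise ValueError(f"article {article.article_id!r} has an empty term pool")
    N = sum(counts.values())
    V_d = len(counts)
    if background_model == "variable_size":
        denom = N + V_d
        return BackgroundModel({t: (c + 1) / denom for t, c in counts.items()}, 0.0, N, V_d)
    if V is None:
        raise ValueError("fixed_size background model requires V")
    if V < V_d:
        raise ValueError(f"fixed vocabulary size V={V} < distinct pool terms V_d={V_d}")
    denom = N + V
    return BackgroundModel({t: (c + 1) / denom for t, c in counts.items()}, 1.0 / denom, N, V_d)


def lm_score(
    sentence_vec: TermVector,
    figure_prob: Mapping[str, float],
    background: BackgroundModel,
    lam: float,
) -> float:
    """Log-odds score of one sentence/figure instance.

    Terms with zero probability under both distributions contribute nothing.
    A zero background probability with positive figure probability (possible
    only under a VariableSize background applied to out-of-pool text) is
    guarded by substituting ``1 / (N + V_d + 1)`` for the background term.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lam must lie in [0, 1]")
    score = 0.0
    eps = 1.0 / (background.N + background.V_d + 1)
    for t in sentence_vec.entries:
        p_b = background.prob(t)
        p_f = figure_prob.get(t, 0.0)
        if p_b == 0.0:
            if p_f == 0.0:
                continue
            logger.debug("zero background probability for %r; applying guard", t)
            p_b = eps
        score += math.log(max(lam + (1.0 - lam) * p_f / p_b, _RATIO_FLOOR))
    return score


# ---------------------------------------------------------------------------
# Vectorized per-article machinery (shared by score_article and fit_lm)
# ---------------------------------------------------------------------------

class _ArticleData:
    """Flattened per-instance term arrays for fast grid evaluation.

    One row per (instance, distinct sentence term): pool count ``n``, and the
    figure's caption-only / referencing-only / pooled probabilities for that
    term (fallbacks already applied).  Every sentence term is in the article
    pool by construction, so background probabilities are strictly positive.
    """

    def __init__(self, article: Article, tokenizer: TokenizerConfig = DEFAULT_TOKENIZER):
        self.article_id = article.article_id
        self.n_s = article.n_sentences
        self.n_f = article.n_figures
        sent_terms = [sorted(set(tokenize(s, tokenizer))) for s in article.sentences]
        self.sent_token_len = np.array(
            [len(tokenize(s, tokenizer)) for s in article.sentences], dtype=float
        )
        pool: dict[str, int] = {}
        for s in article.sentences:
            for t in tokenize(s, tokenizer):
                pool[t] = pool.get(t, 0) + 1
        for f in article.figures:
            for text in [f.caption_text, *f.referencing_paragraphs]:
                for t in tokenize(text, tokenizer):
                    pool[t] = pool.get(t, 0) + 1
        if not pool:
            raise ValueError(f"article {article.article_id!r} has an empty term pool")
        self.N = sum(pool.values())
        self.V_d = len(pool)

        fig_dists = []
        for f in article.figures:
            cap, ref = figure_counts(f, tokenizer)
            fig_dists.append(
                (
                    figure_term_prob(cap, ref, "caption_only"),
                    figure_term_prob(cap, ref, "referencing_only"),
                    figure_term_prob(cap, ref, "pooled"),
                )
            )

        n_rows, pc_rows, pr_rows, pp_rows, inst_idx = [], [], [], [], []
        inst = 0
        inst_sent_len = []
        for j in range(self.n_s):
            terms = sent_terms[j]
            for k in range(self.n_f):
                pc, pr, pp = fig_dists[k]
                for t in terms:
                    n_rows.append(pool[t])
                    pc_rows.append(pc.get(t, 0.0))
                    pr_rows.append(pr.get(t, 0.0))
                    pp_rows.append(pp.get(t, 0.0))
                    inst_idx.append(inst)
                inst_sent_len.append(self.sent_token_len[j])
                inst += 1
        self.n_inst = inst
        self.n_arr = np.array(n_rows, dtype=float)
        self.pc_arr = np.array(pc_rows, dtype=float)
        self.pr_arr = np.array(pr_rows, dtype=float)
        self.pp_arr = np.array(pp_rows, dtype=float)
        self.inst_idx = np.array(inst_idx, dtype=np.intp)
        self.inst_sent_len = np.array(inst_sent_len, dtype=float)
        self.labels = (
            None if article.linkage is None else article.linkage.astype(int).ravel()
        )

    def figure_probs(self, figure_model: str, beta: float | None) -> np.ndarray:
        if figure_model == "caption_only":
            return self.pc_arr
        if figure_model == "referencing_only":
            return self.pr_arr
        if figure_model == "pooled":
            return self.pp_arr
        return beta * self.pc_arr + (1.0 - beta) * self.pr_arr

    def background_probs(self, background_model: str, V: int | None) -> np.ndarray:
        if background_model == "variable_size":
            return (self.n_arr + 1.0) / (self.N + self.V_d)
        if V < self.V_d:
            raise ValueError(
                f"fixed vocabulary size V={V} < distinct pool terms V_d={self.V_d} "
                f"(article {self.article_id!r})"
            )
        return (self.n_arr + 1.0) / (self.N + V)

    def scores(
        self,
        figure_model: str,
        background_model: str,
        lam: float,
        beta: float | None = None,
        V: int | None = None,
    ) -> np.ndarray:
        p_f = self.figure_probs(figure_model, beta)
        p_b = self.background_probs(background_model, V)
        contrib = np.log(np.maximum(lam + (1.0 - lam) * p_f / p_b, _RATIO_FLOOR))
        return np.bincount(self.inst_idx, weights=contrib, minlength=self.n_inst)


def prepare_articles(
    articles: Sequence[Article], tokenizer: TokenizerConfig = DEFAULT_TOKENIZER
) -> list[_ArticleData]:
    """Precompute per-article term arrays (reusable across folds and grids)."""
    return [_ArticleData(a, tokenizer) for a in articles]


def score_article(article: Article, config: LMConfig, *, _data: _ArticleData | None = None) -> ScoreMatrix:
    """LM score matrix ``S`` for one article under a (fitted) configuration."""
    config.validate()
    if config.lam is None:
        raise ValueError("LMConfig.lam is unset; fit or set it first")
    data = _data if _data is not None else _ArticleData(article, config.tokenizer)
    flat = data.scores(
        config.figure_model, config.background_model, config.lam, config.beta, config.V
    )
    return ScoreMatrix(flat.reshape(data.n_s, data.n_f), kind="S")


# ---------------------------------------------------------------------------
# Supervised fitting of lambda, beta and V
# ---------------------------------------------------------------------------

def lambda_grid() -> np.ndarray:
    """The 99 candidate background proportions 0.01, 0.02, ..., 0.99."""
    return np.round(np.arange(1, 100) * 0.01, 2)


def simplex_grid(step_denominator: int = 14) -> list[tuple[float, float]]:
    """(lambda, beta) pairs from the 120 evenly spaced points of the 2-simplex.

    Points are the lattice ``{(i, j, k) >= 0 : i + j + k = 14} / 14`` mapped to
    mixture weights background = i/14, caption = j/14, referencing = k/14,
    i.e. ``lambda = i/14`` and ``beta = j / (j + k)`` (``beta = 1`` at the
    degenerate apex ``lambda = 1``).  With denominator 14 the lattice has
    C(16, 2) = 120 points.
    """
    d = step_denominator
    pts = []
    for i in range(d + 1):
        for j in range(d + 1 - i):
            k = d - i - j
            beta = j / (j + k) if (j + k) > 0 else 1.0
            pts.append((i / d, beta))
    return pts


def max_f1(scores: np.ndarray, labels: np.ndarray) -> float:
    """Maximum F1 over all thresholds on the scores.

    Thresholds sit between distinct score values (ties collapse to one
    step).  F1 = 2*TP / (predicted_positives + actual_positives); an input
    with no positive labels yields 0.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    npos = int(labels.sum())
    if npos == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    tp = np.cumsum(labels[order])
    # valid cut points: after the last occurrence of each distinct value
    is_cut = np.ones(scores.size, dtype=bool)
    is_cut[:-1] = s_sorted[:-1] != s_sorted[1:]
    k = np.arange(1, scores.size + 1)
    f1 = 2.0 * tp[is_cut] / (k[is_cut] + npos)
    return float(f1.max(initial=0.0))


def _mean_max_f1(per_article_scores: list[np.ndarray], data: list[_ArticleData]) -> float:
    vals = [max_f1(s, d.labels) for s, d in zip(per_article_scores, data)]
    return float(np.mean(vals))


def _grid_objective(
    data: list[_ArticleData],
    figure_model: str,
    background_model: str,
    lam: float,
    beta: float | None,
    V: int | None,
) -> float:
    scores = [d.scores(figure_model, background_model, lam, beta, V) for d in data]
    return _mean_max_f1(scores, data)


def _fit_lambda(
    data: list[_ArticleData], figure_model: str, background_model: str, V: int | None
) -> tuple[float, dict]:
    grid = lambda_grid()
    best_lam, best_obj = None, -np.inf
    objs = []
    for lam in grid:  # ascending; >= breaks ties toward larger lambda
        obj = _grid_objective(data, figure_model, background_model, float(lam), None, V)
        objs.append(obj)
        if obj >= best_obj:
            best_obj, best_lam = obj, float(lam)
    return best_lam, {"grid_size": len(grid), "objective": best_obj, "objectives": objs}


def _fit_simplex(
    data: list[_ArticleData], background_model: str, V: int | None
) -> tuple[float, float, dict]:
    grid = simplex_grid()
    best, best_obj = None, -np.inf
    for lam, beta in sorted(grid):  # ascending lambda; ties toward larger lambda
        obj = _grid_objective(data, "mixture", background_model, lam, beta, V)
        if obj >= best_obj:
            best_obj, best = obj, (lam, beta)
    return best[0], best[1], {"grid_size": len(grid), "objective": best_obj}


def _length_score_correlation(
    data: list[_ArticleData],
    figure_model: str,
    background_model: str,
    lam: float,
    beta: float | None,
    V: int | None,
) -> float:
    scores = np.concatenate(
        [d.scores(figure_model, background_model, lam, beta, V) for d in data]
    )
    lengths = np.concatenate([d.inst_sent_len for d in data])
    if scores.std() == 0.0 or lengths.std() == 0.0:
        return 0.0
    return float(np.corrcoef(lengths, scores)[0, 1])


def v_grid(data: list[_ArticleData]) -> list[int]:
    """Candidate fixed vocabulary sizes: a geometric ladder above the largest
    per-article distinct-term count, plus a few large absolute sizes."""
    base = max(d.V_d for d in data)
    cands = {base * (2**i) for i in range(7)} | {5000, 10000, 20000}
    return sorted(v for v in cands if v >= base)


def _fit_V(
    data: list[_ArticleData], figure_model: str, lam: float, beta: float | None
) -> tuple[int, dict]:
    grid = v_grid(data)
    corrs = [
        abs(_length_score_correlation(data, figure_model, "fixed_size", lam, beta, V))
        for V in grid
    ]
    best = int(np.argmin(corrs))  # first minimum -> smallest such V
    return grid[best], {"v_grid": grid, "abs_correlations": corrs}


def fit_lm(
    train_corpus: Sequence[Article],
    figure_model: str = "mixture",
    background_model: str = "fixed_size",
    tokenizer: TokenizerConfig = DEFAULT_TOKENIZER,
    *,
    _data: list[_ArticleData] | None = None,
) -> LMConfig:
    """Fit mixing proportions (and ``V``) on an annotated training corpus.

    Staged procedure: (i) non-mixture VariableSize models grid-search
    ``lambda`` over 99 values maximizing mean per-article max-F1; (ii)
    FixedSize models temporarily adopt the VariableSize ``lambda``, choose
    ``V`` minimizing |Pearson r(sentence length, score)| over training
    instances, then re-search ``lambda``; (iii) mixture models search
    ``(lambda, beta)`` jointly over the 120-point simplex lattice, with the
    analogous ``V`` stage for FixedSize.  Ties break toward larger ``lambda``
    (more smoothing).
    """
    if figure_model not in FIGURE_MODELS:
        raise ValueError(f"unknown figure_model {figure_model!r}")
    if background_model not in BACKGROUND_MODELS:
        raise ValueError(f"unknown background_model {background_model!r}")
    data = _data if _data is not None else prepare_articles(train_corpus, tokenizer)
    if not data:
        raise ValueError("training corpus is empty")
    if any(d.labels is None for d in data):
        raise ValueError("fit_lm requires gold linkage matrices on all training articles")

    diagnostics: dict = {}
    if figure_model != "mixture":
        lam_var, diag = _fit_lambda(data, figure_model, "variable_size", None)
        diagnostics["lambda_search_variable"] = {
            "grid_size": diag["grid_size"], "objective": diag["objective"]
        }
        if background_model == "variable_size":
            cfg = LMConfig(figure_model, background_model, lam=lam_var, tokenizer=tokenizer)
        else:
            V, vdiag = _fit_V(data, figure_model, lam_var, None)
            lam, diag2 = _fit_lambda(data, figure_model, "fixed_size", V)
            diagnostics["v_search"] = vdiag
            diagnostics["lambda_search_fixed"] = {
                "grid_size": diag2["grid_size"], "objective": diag2["objective"]
            }
            cfg = LMConfig(figure_model, background_model, lam=lam, V=V, tokenizer=tokenizer)
    else:
        lam_var, beta_var, diag = _fit_simplex(data, "variable_size", None)
        diagnostics["simplex_search_variable"] = diag
        if background_model == "variable_size":
            cfg = LMConfig(
                figure_model, background_model, lam=lam_var, beta=beta_var, tokenizer=tokenizer
            )
        else:
            V, vdiag = _fit_V(data, "mixture", lam_var, beta_var)
            lam, beta, diag2 = _fit_simplex(data, "fixed_size", V)
            diagnostics["v_search"] = vdiag
            diagnostics["simplex_search_fixed"] = diag2
            cfg = LMConfig(
                figure_model, background_model, lam=lam, beta=beta, V=V, tokenizer=tokenizer
            )
    logger.info(
        "fit_lm(%s, %s): lambda=%s beta=%s V=%s",
        figure_model, background_model, cfg.lam, cfg.beta, cfg.V,
    )
    cfg.diagnostics = diagnostics
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# TFIDF cosine baseline
# ---------------------------------------------------------------------------

def tfidf_baseline_score(
    article: Article, tokenizer: TokenizerConfig = DEFAULT_TOKENIZER
) -> ScoreMatrix:
    """Cosine similarity between TFIDF vectors of each sentence and each
    figure's pooled caption + referencing text.

    IDF is computed over the article's own sentence and figure documents
    with the standard smoothed form ``idf = ln((1 + n_docs)/(1 + df)) + 1``
    (strictly positive, so identical texts score exactly 1).  Sentence term
    frequencies are binary (set of words), figure frequencies are raw
    counts.  This is an approximate reimplementation of the standard
    unsupervised baseline for this task, not a faithful replication of any
    particular system.
    """
    sent_docs = [sentence_vector(s, tokenizer).entries for s in article.sentences]
    fig_docs = []
    for f in article.figures:
        cap, ref = figure_counts(f, tokenizer)
        pooled = dict(cap.entries)
        for t, c in ref.entries.items():
            pooled[t] = pooled.get(t, 0) + c
        fig_docs.append(pooled)
    docs = sent_docs + fig_docs
    n_docs = len(docs)
    df: dict[str, int] = {}
    for d in docs:
        for t in d:
            df[t] = df.get(t, 0) + 1
    idf = {t: math.log((1 + n_docs) / (1 + c)) + 1.0 for t, c in df.items()}

    def weight(doc: Mapping[str, int]) -> dict[str, float]:
        return {t: c * idf[t] for t, c in doc.items()}

    def cosine(a: Mapping[str, float], b: Mapping[str, float]) -> float:
        dot = sum(w * b[t] for t, w in a.items() if t in b)
        na = math.sqrt(sum(w * w for w in a.values()))
        nb = math.sqrt(sum(w * w for w in b.values()))
        if na == 0.0 or nb == 0.0:
            return 0.0
        return dot / (na * nb)

    svecs = [weight(d) for d in sent_docs]
    fvecs = [weight(d) for d in fig_docs]
    values = np.array([[cosine(sv, fv) for fv in fvecs] for sv in svecs])
    return ScoreMatrix(values, kind="TFIDF")
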