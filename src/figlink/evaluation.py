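"""Ranking metrics, resampling tests, agreement statistics and
leave-one-article-out cross-validation.

Metrics follow information-retrieval conventions: precision, recall,
false-positive rate and F1 = 2RP/(R+P) from thresholded predictions; PR and
ROC curves by sweeping the score threshold (ties grouped into one step);
AROC by the trapezoid rule, so label-independent constant scores give
exactly 0.5.  Two aggregation schemes are used throughout: *whole-corpus*
(pool every sentence/figure instance, then compute) and *per-article*
(compute within each article, then average) — the per-article scheme is the
operationally relevant one since a browsing system ranks figures one
article at a time.

"Clicks" estimates saved user effort: for a sentence whose last truly
linked figure sits at document position ``m``, a user clicking figures in
document order needs ``m`` clicks, while a user following the system
ranking needs ``r`` — the smallest prefix of the ranking containing all the
sentence's linked figures; the saving ``m - r`` is averaged over all
sentences (sentences with no links contribute zero).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus import Article
from .lm import ScoreMatrix, max_f1, prepare_articles
from .pipeline import LinkagePipeline

logger = logging.getLogger("figlink")

__all__ = [
    "AgreementStats",
    "EvalReport",
    "PermutationTestResult",
    "agreement_stats",
    "article_permutation_test",
    "clicks_saved",
    "confusion_metrics",
    "curves_and_aroc",
    "evaluate_scores",
    "loao_crossval",
    "max_f1_per_article",
    "paired_ttest",
    "precision_at_reference",
]


# ---------------------------------------------------------------------------
# Point metrics and curves
# ---------------------------------------------------------------------------

def confusion_metrics(predicted, gold) -> tuple[float, float, float, float]:
    """(precision, recall, false-positive rate, F1) of binary predictions.

    Conventions: precision with zero predicted positives is reported as 0
    with a warning; F1 is 0 when P + R = 0; FPR with zero negatives is 0.
    """
    pred = np.asarray(predicted, dtype=int).ravel()
    y = np.asarray(gold, dtype=int).ravel()
    if pred.shape != y.shape:
        raise ValueError("predicted and gold must have equal length")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision reported as 0", stacklevel=2)
        p = 0.0
    else:
        p = tp / (tp + fp)
    r = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    f1 = 2 * r * p / (r + p) if (r + p) > 0 else 0.0
    return p, r, fpr, f1


@dataclass
class Curves:
    """ROC and PR curve points plus the area under the ROC curve."""

    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    pr_recall: np.ndarray
    pr_precision: np.ndarray
    aroc: float


def curves_and_aroc(scores, gold) -> Curves:
    """Threshold-sweep ROC / PR curves and trapezoid AROC.

    Thresholds sit between distinct score values; tied scores enter or
    leave the positive set together.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(gold, dtype=int).ravel()
    npos, nneg = int(y.sum()), int((1 - y).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("curves require at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    is_cut = np.ones(s.size, dtype=bool)
    is_cut[:-1] = s_sorted[:-1] != s_sorted[1:]
    tp = np.cumsum(y_sorted)[is_cut]
    k = np.arange(1, s.size + 1)[is_cut]
    fp = k - tp
    tpr = np.concatenate([[0.0], tp / npos])
    fpr = np.concatenate([[0.0], fp / nneg])
    aroc = float(np.trapezoid(tpr, fpr))
    precision = tp / k
    return Curves(
        roc_fpr=fpr, roc_tpr=tpr, pr_recall=tpr[1:], pr_precision=precision, aroc=aroc
    )


def _flatten_sorted(values: np.ndarray, article_idx: int | None = None):
    """(sort keys, flat values) with the deterministic (score desc, article,
    j, k) tie order used by every top-n selection."""
    n_s, n_f = values.shape
    j = np.repeat(np.arange(n_s), n_f)
    k = np.tile(np.arange(n_f), n_s)
    return j, k


def precision_at_reference(
    scores: Sequence[ScoreMatrix | np.ndarray],
    gold: Sequence[np.ndarray],
    mode: str = "per_article",
) -> float:
    """Precision when the number of predicted links equals the number of
    abstract sentences.

    Per-article: predict the top ``n_s(a)`` instances of each article and
    average the precisions.  Whole-corpus: predict the top ``sum_a n_s(a)``
    pooled instances.  Ties break deterministically by (article order, j, k).
    """
    mats = [m.values if isinstance(m, ScoreMatrix) else np.asarray(m) for m in scores]
    golds = [np.asarray(g, dtype=int) for g in gold]
    if mode == "per_article":
        precs = []
        for m, g in zip(mats, golds):
            n_s = m.shape[0]
            flat = m.ravel()
            order = np.argsort(-flat, kind="stable")  # stable: ties by (j, k)
            top = order[:n_s]
            precs.append(g.ravel()[top].sum() / n_s)
        return float(np.mean(precs))
    if mode == "whole_corpus":
        flat = np.concatenate([m.ravel() for m in mats])
        labels = np.concatenate([g.ravel() for g in golds])
        budget = sum(m.shape[0] for m in mats)
        order = np.argsort(-flat, kind="stable")
        top = order[:budget]
        return float(labels[top].sum() / budget)
    raise ValueError(f"unknown mode {mode!r}")


def max_f1_per_article(
    scores: Sequence[ScoreMatrix | np.ndarray], gold: Sequence[np.ndarray]
) -> float:
    """Mean over articles of the maximum F1 over score thresholds.

    An article with no gold links contributes F1 = 0 (logged).
    """
    vals = []
    for m, g in zip(scores, gold):
        v = m.values if isinstance(m, ScoreMatrix) else np.asarray(m)
        g = np.asarray(g, dtype=int)
        if g.sum() == 0:
            logger.debug("article with no gold links contributes max-F1 = 0")
            vals.append(0.0)
        else:
            vals.append(max_f1(v.ravel(), g.ravel()))
    return float(np.mean(vals))


def clicks_saved(
    scores: Sequence[ScoreMatrix | np.ndarray], gold: Sequence[np.ndarray]
) -> float:
    """Mean clicks saved per sentence by following the system's figure
    ranking instead of document order."""
    saved, n_sentences = 0.0, 0
    for m, g in zip(scores, gold):
        v = m.values if isinstance(m, ScoreMatrix) else np.asarray(m)
        g = np.asarray(g, dtype=int)
        n_s, n_f = v.shape
        for j in range(n_s):
            n_sentences += 1
            linked = np.flatnonzero(g[j])
            if linked.size == 0:
                continue
            m_last = int(linked.max()) + 1
            order = np.argsort(-v[j], kind="stable")  # ties by document order
            rank = np.empty(n_f, dtype=int)
            rank[order] = np.arange(1, n_f + 1)
            r = int(rank[linked].max())
            saved += m_last - r
    return saved / n_sentences if n_sentences else 0.0


# ---------------------------------------------------------------------------
# Resampling and agreement
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    achieved_per_article_aroc: float
    achieved_per_article_precision: float
    whole_corpus_aroc: float
    whole_corpus_precision: float
    null_aroc: np.ndarray
    null_precision: np.ndarray
    n_perm: int

    def rank_of_achieved(self, metric: str = "aroc") -> float:
        """Fraction of permutations with a null value >= the achieved
        per-article value."""
        null = self.null_aroc if metric == "aroc" else self.null_precision
        achieved = (
            self.achieved_per_article_aroc
            if metric == "aroc"
            else self.achieved_per_article_precision
        )
        return float((null >= achieved).mean())


def _per_article_aroc_precision(
    mats: Sequence[np.ndarray], labels: Sequence[np.ndarray]
) -> tuple[float, float]:
    arocs, precs = [], []
    for v, y in zip(mats, labels):
        n_s = v.shape[0]
        flat, yflat = v.ravel(), y.ravel()
        if 0 < yflat.sum() < yflat.size:
            arocs.append(curves_and_aroc(flat, yflat).aroc)
        order = np.argsort(-flat, kind="stable")
        precs.append(yflat[order[:n_s]].sum() / n_s)
    return float(np.mean(arocs)) if arocs else float("nan"), float(np.mean(precs))


def article_permutation_test(
    scores: Sequence[ScoreMatrix | np.ndarray],
    gold: Sequence[np.ndarray],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Null distribution of per-article mean AROC and precision under random
    reassignment of instances to articles.

    Each permutation shuffles the pooled linked instances among the corpus's
    linked slots and the pooled non-linked instances among the non-linked
    slots, preserving every article's instance count, linked count and
    shape.  Whole-corpus values are invariant under this scheme, so
    comparing the achieved per-article value against the null isolates the
    article effect.  Deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(scores) < 2:
        raise ValueError("permutation test requires at least 2 articles")
    mats = [m.values if isinstance(m, ScoreMatrix) else np.asarray(m) for m in scores]
    labels = [np.asarray(g, dtype=int) for g in gold]
    ach_aroc, ach_prec = _per_article_aroc_precision(mats, labels)
    flat = np.concatenate([m.ravel() for m in mats])
    yflat = np.concatenate([g.ravel() for g in labels])
    wc = curves_and_aroc(flat, yflat)
    wc_prec = precision_at_reference(mats, labels, "whole_corpus")
    pos_pool = flat[yflat == 1]
    neg_pool = flat[yflat == 0]
    shapes = [m.shape for m in mats]
    n_pos = [int(g.sum()) for g in labels]

    rng = np.random.default_rng(seed)
    null_aroc = np.empty(n_perm)
    null_prec = np.empty(n_perm)
    for p in range(n_perm):
        pos = rng.permutation(pos_pool)
        neg = rng.permutation(neg_pool)
        pm, py, ip, ineg = [], [], 0, 0
        for shape, np_a in zip(shapes, n_pos):
            n_inst = shape[0] * shape[1]
            vals = np.concatenate([pos[ip : ip + np_a], neg[ineg : ineg + n_inst - np_a]])
            lab = np.concatenate(
                [np.ones(np_a, dtype=int), np.zeros(n_inst - np_a, dtype=int)]
            )
            ip += np_a
            ineg += n_inst - np_a
            pm.append(vals.reshape(shape))
            py.append(lab.reshape(shape))
        null_aroc[p], null_prec[p] = _per_article_aroc_precision(pm, py)
    return PermutationTestResult(
        achieved_per_article_aroc=ach_aroc,
        achieved_per_article_precision=ach_prec,
        whole_corpus_aroc=wc.aroc,
        whole_corpus_precision=wc_prec,
        null_aroc=null_aroc,
        null_precision=null_prec,
        n_perm=n_perm,
    )


@dataclass
class AgreementStats:
    percent_agreement: float
    kappa: float
    row_link_rate: float
    col_link_rate: float
    disagreement_rate: float


def agreement_stats(contingency) -> AgreementStats:
    """Inter-annotator agreement from a 2x2 contingency table.

    ``contingency[a, b]`` counts instances the row annotator labelled ``a``
    and the column annotator labelled ``b`` (0 = non-linked, 1 = linked).
    Cohen's kappa corrects observed agreement for the chance agreement
    expected from the marginal link rates.
    """
    t = np.asarray(contingency, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("contingency must be a non-negative 2x2 table")
    n = t.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    p_o = (t[0, 0] + t[1, 1]) / n
    row = t.sum(axis=1) / n
    col = t.sum(axis=0) / n
    p_e = float(row @ col)
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    return AgreementStats(
        percent_agreement=float(p_o),
        kappa=float(kappa),
        row_link_rate=float(row[1]),
        col_link_rate=float(col[1]),
        disagreement_rate=float(1.0 - p_o),
    )


def paired_ttest(metric_a, metric_b) -> float:
    """Two-sided paired t-test p-value on per-article metric vectors."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.std(d) == 0.0:
        if d[0] == 0.0:
            warnings.warn(
                "identical metric vectors; p reported as 1", stacklevel=2
            )
            return 1.0
        # a perfectly consistent nonzero difference: infinitely strong evidence
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# Report assembly and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-article and whole-corpus performance of one scoring system."""

    model: str
    n_articles: int
    per_article_aroc: list[float]
    per_article_max_f1: list[float]
    per_article_precision: list[float]
    mean_aroc: float
    mean_max_f1: float
    mean_precision: float
    whole_corpus_aroc: float
    whole_corpus_max_f1: float
    whole_corpus_precision: float
    clicks: float
    roc_curve: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    pr_curve: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "n_articles": self.n_articles,
            "per_article": {
                "aroc": self.per_article_aroc,
                "max_f1": self.per_article_max_f1,
                "precision": self.per_article_precision,
                "mean_aroc": self.mean_aroc,
                "mean_max_f1": self.mean_max_f1,
                "mean_precision": self.mean_precision,
            },
            "whole_corpus": {
                "aroc": self.whole_corpus_aroc,
                "max_f1": self.whole_corpus_max_f1,
                "precision": self.whole_corpus_precision,
            },
            "clicks": self.clicks,
        }
        return d


def evaluate_scores(
    articles: Sequence[Article],
    scores: Sequence[ScoreMatrix | np.ndarray],
    model: str = "scores",
) -> EvalReport:
    """Assemble the full report for predicted score matrices against gold.

    Per-article AROC is undefined for single-class articles; those articles
    are excluded from the AROC mean (logged) but still contribute to the
    other metrics.
    """
    mats = [m.values if isinstance(m, ScoreMatrix) else np.asarray(m) for m in scores]
    golds = [a.linkage.astype(int) for a in articles]
    pa_aroc, pa_f1, pa_prec = [], [], []
    for v, g in zip(mats, golds):
        flat, yflat = v.ravel(), g.ravel()
        if 0 < yflat.sum() < yflat.size:
            pa_aroc.append(curves_and_aroc(flat, yflat).aroc)
        else:
            logger.debug("single-class article excluded from per-article AROC")
            pa_aroc.append(float("nan"))
        pa_f1.append(max_f1(flat, yflat) if yflat.sum() else 0.0)
        order = np.argsort(-flat, kind="stable")
        pa_prec.append(float(yflat[order[: v.shape[0]]].sum() / v.shape[0]))
    flat_all = np.concatenate([m.ravel() for m in mats])
    y_all = np.concatenate([g.ravel() for g in golds])
    wc = curves_and_aroc(flat_all, y_all)
    return EvalReport(
        model=model,
        n_articles=len(articles),
        per_article_aroc=pa_aroc,
        per_article_max_f1=pa_f1,
        per_article_precision=pa_prec,
        mean_aroc=float(np.nanmean(pa_aroc)),
        mean_max_f1=float(np.mean(pa_f1)),
        mean_precision=float(np.mean(pa_prec)),
        whole_corpus_aroc=wc.aroc,
        whole_corpus_max_f1=max_f1(flat_all, y_all),
        whole_corpus_precision=precision_at_reference(mats, golds, "whole_corpus"),
        clicks=clicks_saved(mats, golds),
        roc_curve=(wc.roc_fpr, wc.roc_tpr),
        pr_curve=(wc.pr_recall, wc.pr_precision),
    )


def loao_crossval(
    corpus: Sequence[Article],
    model: str = "crf-sis",
    **pipeline_kwargs,
) -> tuple[EvalReport, list[ScoreMatrix]]:
    """Leave-one-article-out cross-validation.

    For each fold, every learnable parameter (lambda, beta, V, distance
    bins, transitions, Gaussian calibration, CRF weights) is fitted on the
    other articles and the held-out article is scored; the pooled held-out
    scores feed one report under both aggregation schemes.  Returns the
    report and the per-article held-out score matrices (article order).
    """
    if len(corpus) < 2:
        raise ValueError("cross-validation requires at least 2 articles")
    if any(a.linkage is None for a in corpus):
        raise ValueError("cross-validation requires gold linkage on all articles")
    tokenizer = pipeline_kwargs.get("tokenizer")
    probe = LinkagePipeline(model=model, **pipeline_kwargs)
    prepared = {
        a.article_id: d
        for a, d in zip(corpus, prepare_articles(corpus, probe.tokenizer))
    }
    held_out: list[ScoreMatrix] = []
    for i, test_article in enumerate(corpus):
        train = [a for j, a in enumerate(corpus) if j != i]
        pipe = LinkagePipeline(model=model, **pipeline_kwargs)
        pipe.fit(train, _prepared=prepared)
        held_out.append(pipe.score(test_article, _data=prepared[test_article.article_id]))
    report = evaluate_scores(corpus, held_out, model=model)
    return report, held_out
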