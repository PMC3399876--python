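"""Data model for annotated articles: tokenization, term vectors, corpus I/O.

An annotated article consists of its ordered abstract sentences, its ordered
figures (each with a caption and the body paragraphs that reference it), and
optionally a binary linkage matrix ``L`` where ``L[j, k] = 1`` means abstract
sentence ``j`` supports / is supported by figure ``k``.  Sentences and figures
are numbered 1-based in document order in all external representations;
internally the linkage matrix is a 0-based numpy array.

Text is represented two ways: figures as bags of words (term counts) and
abstract sentences as sets of words (binary indicators).
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("figlink")

__all__ = [
    "Article",
    "CorpusError",
    "CorpusStats",
    "Figure",
    "TermVector",
    "TokenizerConfig",
    "corpus_stats",
    "figure_counts",
    "read_corpus",
    "sentence_vector",
    "tokenize",
    "write_corpus",
]


class CorpusError(ValueError):
    """Raised when a corpus file or article violates the schema."""


# Small built-in English stopword list; stopword removal is off by default.
STOPWORDS = frozenset(
    """a an and are as at be but by for from has have in is it its of on or
    that the their there these this to was were which with we our not no""".split()
)

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


@dataclass(frozen=True)
class TokenizerConfig:
    """Tokenizer settings.

    lowercase alphanumeric split, no stemming; stopword removal and a minimum
    token length are available but off by default so that behaviour is fully
    reproducible from the recorded config.
    """

    remove_stopwords: bool = False
    min_token_length: int = 1

    def to_dict(self) -> dict:
        return {
            "remove_stopwords": self.remove_stopwords,
            "min_token_length": self.min_token_length,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TokenizerConfig":
        return cls(
            remove_stopwords=bool(d.get("remove_stopwords", False)),
            min_token_length=int(d.get("min_token_length", 1)),
        )


DEFAULT_TOKENIZER = TokenizerConfig()


def tokenize(text: str, config: TokenizerConfig = DEFAULT_TOKENIZER) -> list[str]:
    """Split ``text`` into lowercase alphanumeric terms.

    Deterministic for a fixed config; empty input yields an empty list.
    """
    terms = [t for t in _TOKEN_RE.split(text.lower()) if t]
    if config.min_token_length > 1:
        terms = [t for t in terms if len(t) >= config.min_token_length]
    if config.remove_stopwords:
        terms = [t for t in terms if t not in STOPWORDS]
    return terms


@dataclass
class TermVector:
    """Sparse term vector: term -> count, plus the source token total.

    Sentence vectors are binary (each present term maps to 1) while figure
    vectors hold raw occurrence counts.  ``total`` is the number of source
    tokens, which for a binary sentence vector is the number of distinct terms.
    """

    entries: dict[str, int] = field(default_factory=dict)
    total: int = 0

    def __post_init__(self) -> None:
        if self.total == 0 and self.entries:
            self.total = sum(self.entries.values())


def sentence_vector(sentence: str, config: TokenizerConfig = DEFAULT_TOKENIZER) -> TermVector:
    """Binary set-of-words vector for an abstract sentence."""
    terms = set(tokenize(sentence, config))
    return TermVector({t: 1 for t in sorted(terms)}, total=len(terms))


@dataclass
class Figure:
    """A figure (or table): its caption and the body paragraphs citing it."""

    caption_text: str = ""
    referencing_paragraphs: list[str] = field(default_factory=list)


def figure_counts(
    figure: Figure, config: TokenizerConfig = DEFAULT_TOKENIZER
) -> tuple[TermVector, TermVector]:
    """Bag-of-words count vectors for a figure's caption and referencing text.

    Referencing paragraphs are pooled into a single vector.  Totals are the
    raw token counts of each source.
    """
    cap = Counter(tokenize(figure.caption_text, config))
    ref: Counter[str] = Counter()
    for para in figure.referencing_paragraphs:
        ref.update(tokenize(para, config))
    return (
        TermVector(dict(cap), total=sum(cap.values())),
        TermVector(dict(ref), total=sum(ref.values())),
    )


@dataclass
class Article:
    """An annotated article.

    ``linkage`` (if present) is an ``n_s x n_f`` binary numpy array; row ``j-1``
    corresponds to abstract sentence ``j`` and column ``k-1`` to figure ``k``.
    """

    article_id: str
    sentences: list[str]
    figures: list[Figure]
    linkage: np.ndarray | None = None

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def n_figures(self) -> int:
        return len(self.figures)

    def validate(self) -> None:
        if not self.sentences:
            raise CorpusError(f"article {self.article_id!r}: field 'sentences' is empty")
        if not self.figures:
            raise CorpusError(f"article {self.article_id!r}: field 'figures' is empty")
        if self.linkage is not None:
            L = np.asarray(self.linkage)
            shape = (len(self.sentences), len(self.figures))
            if L.shape != shape:
                raise CorpusError(
                    f"article {self.article_id!r}: field 'linkage' has shape "
                    f"{L.shape}, expected {shape} (sentences x figures)"
                )
            if not np.isin(L, (0, 1)).all():
                raise CorpusError(
                    f"article {self.article_id!r}: field 'linkage' entries must be 0 or 1"
                )

    def __post_init__(self) -> None:
        if self.linkage is not None:
            self.linkage = np.asarray(self.linkage, dtype=np.int8)
        self.validate()


def _article_to_dict(article: Article) -> dict:
    d: dict = {
        "article_id": article.article_id,
        "sentences": list(article.sentences),
        "figures": [
            {
                "caption": f.caption_text,
                "referencing_paragraphs": list(f.referencing_paragraphs),
            }
            for f in article.figures
        ],
    }
    if article.linkage is not None:
        d["linkage"] = article.linkage.astype(int).tolist()
    return d


def _article_from_dict(d: Mapping, index: int) -> Article:
    if not isinstance(d, Mapping):
        raise CorpusError(f"corpus entry {index}: expected an object")
    aid = d.get("article_id")
    if not isinstance(aid, str) or not aid:
        raise CorpusError(f"corpus entry {index}: field 'article_id' must be a non-empty string")
    sentences = d.get("sentences")
    if not isinstance(sentences, list) or not all(isinstance(s, str) for s in sentences):
        raise CorpusError(f"article {aid!r}: field 'sentences' must be a list of strings")
    raw_figures = d.get("figures")
    if not isinstance(raw_figures, list):
        raise CorpusError(f"article {aid!r}: field 'figures' must be a list")
    figures = []
    for i, rf in enumerate(raw_figures, start=1):
        if not isinstance(rf, Mapping):
            raise CorpusError(f"article {aid!r}: figure {i} must be an object")
        caption = rf.get("caption", "")
        paras = rf.get("referencing_paragraphs", [])
        if not isinstance(caption, str):
            raise CorpusError(f"article {aid!r}: figure {i} field 'caption' must be a string")
        if not isinstance(paras, list) or not all(isinstance(p, str) for p in paras):
            raise CorpusError(
                f"article {aid!r}: figure {i} field 'referencing_paragraphs' "
                "must be a list of strings"
            )
        figures.append(Figure(caption_text=caption, referencing_paragraphs=list(paras)))
    linkage = d.get("linkage")
    if linkage is not None:
        try:
            linkage = np.asarray(linkage, dtype=np.int8)
        except (TypeError, ValueError) as exc:
            raise CorpusError(f"article {aid!r}: field 'linkage' is not a matrix") from exc
        if linkage.ndim != 2:
            raise CorpusError(f"article {aid!r}: field 'linkage' must be 2-dimensional")
    return Article(article_id=aid, sentences=list(sentences), figures=figures, linkage=linkage)


def read_corpus(path: str | Path) -> list[Article]:
    """Read a JSON corpus (top-level list of article objects)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise CorpusError("corpus file must contain a top-level JSON list of articles")
    return [_article_from_dict(d, i) for i, d in enumerate(data)]


def write_corpus(articles: Sequence[Article], path: str | Path) -> None:
    """Write articles to a JSON corpus file (round-trips through read_corpus)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([_article_to_dict(a) for a in articles], fh, indent=1)


@dataclass
class CorpusStats:
    n_articles: int
    n_sentences: int
    n_figures: int
    n_instances: int
    n_linked: int
    linked_fraction: float
    sentence_degree_hist: dict[int, int]
    figure_degree_hist: dict[int, int]


def corpus_stats(corpus: Iterable[Article]) -> CorpusStats:
    """Summary counts over an annotated corpus.

    Instances are all sentence/figure pairs; degrees are per-sentence and
    per-figure link counts.  Every article must carry a linkage matrix.
    """
    n_articles = n_sent = n_fig = n_inst = n_linked = 0
    sdeg: Counter[int] = Counter()
    fdeg: Counter[int] = Counter()
    for a in corpus:
        if a.linkage is None:
            raise CorpusError(f"article {a.article_id!r}: field 'linkage' is required for stats")
        L = a.linkage
        n_articles += 1
        n_sent += a.n_sentences
        n_fig += a.n_figures
        n_inst += a.n_sentences * a.n_figures
        n_linked += int(L.sum())
        sdeg.update(L.sum(axis=1).tolist())
        fdeg.update(L.sum(axis=0).tolist())
    if n_articles == 0:
        raise CorpusError("corpus is empty")
    return CorpusStats(
        n_articles=n_articles,
        n_sentences=n_sent,
        n_figures=n_fig,
        n_instances=n_inst,
        n_linked=n_linked,
        linked_fraction=n_linked / n_inst if n_inst else 0.0,
        sentence_degree_hist=dict(sorted(sdeg.items())),
        figure_degree_hist=dict(sorted(fdeg.items())),
    )
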