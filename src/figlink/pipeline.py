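"""End-to-end linkage predictors composing the LM, DM, HMM and CRF pieces.

A pipeline is specified by a model name: "dm" (distance only), "lm"
(language model only), "lm+dm" (independent per-instance combination),
"hmm-sis" / "hmm-fis" / "crf-sis" / "crf-fis" (collective sequence models
whose emissions are calibrated LM or LM+DM scores), or "tfidf" (the
unsupervised cosine baseline).  ``fit`` learns every trainable parameter
from an annotated corpus; ``score`` produces an ``n_s x n_f`` score matrix
for a (possibly unannotated) article.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import Article, TokenizerConfig
from .crf import CRFModel, predict_crf, train_crf
from .distance import DistanceModel, combine_scores, dm_score_matrix, fit_dm
from .hmm import HMMModel, fit_hmm, predict_hmm
from .lm import (
    LMConfig,
    ScoreMatrix,
    _ArticleData,
    fit_lm,
    prepare_articles,
    score_article,
    tfidf_baseline_score,
)

logger = logging.getLogger("figlink")

__all__ = ["MODEL_NAMES", "LinkagePipeline"]

MODEL_NAMES = ("dm", "lm", "lm+dm", "hmm-sis", "hmm-fis", "crf-sis", "crf-fis", "tfidf")


@dataclass
class LinkagePipeline:
    """A trainable sentence/figure linkage predictor.

    ``score_source`` selects the emission input of the sequence models:
    "z" (combined LM+DM scores, the default) or "s" (LM scores only).
    """

    model: str = "crf-sis"
    figure_model: str = "mixture"
    background_model: str = "fixed_size"
    score_source: str = "z"
    hmm_start: str = "learned"
    d_max: int = 2
    l2: float = 1e-2
    tokenizer: TokenizerConfig = field(default_factory=TokenizerConfig)

    lm_config: LMConfig | None = field(default=None, repr=False)
    dm: DistanceModel | None = field(default=None, repr=False)
    hmm: HMMModel | None = field(default=None, repr=False)
    crf: CRFModel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODEL_NAMES}")
        if self.score_source not in ("s", "z"):
            raise ValueError("score_source must be 's' or 'z'")

    # -- which components this model needs -------------------------------
    @property
    def _needs_lm(self) -> bool:
        return self.model not in ("dm", "tfidf")

    @property
    def _needs_dm(self) -> bool:
        if self.model in ("dm", "lm+dm"):
            return True
        return self.model.startswith(("hmm", "crf")) and self.score_source == "z"

    @property
    def _variant(self) -> str | None:
        if self.model.startswith(("hmm", "crf")):
            return self.model.split("-")[1]
        return None

    # ---------------------------------------------------------------------
    def fit(
        self,
        train_corpus: Sequence[Article],
        _prepared: Mapping[str, _ArticleData] | None = None,
    ) -> "LinkagePipeline":
        """Fit all learnable parameters on an annotated training corpus.

        Components that are already set (``lm_config``, ``dm``) are reused,
        so several sequence models can share one fitted LM/DM; clear them to
        refit from scratch.
        """
        if self.model == "tfidf":
            return self
        if any(a.linkage is None for a in train_corpus):
            raise ValueError("training requires gold linkage matrices on all articles")
        data = (
            [_prepared[a.article_id] for a in train_corpus]
            if _prepared is not None
            else prepare_articles(train_corpus, self.tokenizer)
        )
        if self._needs_lm and self.lm_config is None:
            self.lm_config = fit_lm(
                train_corpus, self.figure_model, self.background_model,
                self.tokenizer, _data=data,
            )
        if self._needs_dm and self.dm is None:
            self.dm = fit_dm(train_corpus)
        if self._variant is not None:
            train_scores = [
                self._base_scores(a, _data=d) for a, d in zip(train_corpus, data)
            ]
            if self.model.startswith("hmm"):
                self.hmm = fit_hmm(train_corpus, train_scores, self._variant, self.hmm_start)
            else:
                self.crf = train_crf(
                    train_corpus, train_scores, self._variant, self.d_max, self.l2
                )
        return self

    def _base_scores(self, article: Article, _data: _ArticleData | None = None) -> ScoreMatrix:
        """LM (or LM+DM) scores feeding a sequence model's emissions."""
        S = score_article(article, self.lm_config, _data=_data)
        if self.score_source == "z":
            return combine_scores(S, dm_score_matrix(article, self.dm))
        return S

    def score(self, article: Article, _data: _ArticleData | None = None) -> ScoreMatrix:
        """Linkage score matrix for one article (gold linkage never used)."""
        if self.model == "tfidf":
            return tfidf_baseline_score(article, self.tokenizer)
        if self.model == "dm":
            if self.dm is None:
                raise ValueError("pipeline is not fitted")
            return dm_score_matrix(article, self.dm)
        if self.lm_config is None:
            raise ValueError("pipeline is not fitted")
        if self.model == "lm":
            return score_article(article, self.lm_config, _data=_data)
        if self.model == "lm+dm":
            S = score_article(article, self.lm_config, _data=_data)
            return combine_scores(S, dm_score_matrix(article, self.dm))
        z = self._base_scores(article, _data=_data)
        if self.model.startswith("hmm"):
            return predict_hmm(self.hmm, z)
        return predict_crf(self.crf, z)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "figure_model": self.figure_model,
            "background_model": self.background_model,
            "score_source": self.score_source,
            "hmm_start": self.hmm_start,
            "d_max": self.d_max,
            "l2": self.l2,
            "tokenizer": self.tokenizer.to_dict(),
            "lm_config": self.lm_config.to_dict() if self.lm_config else None,
            "dm": self.dm.to_dict() if self.dm else None,
            "hmm": self.hmm.to_dict() if self.hmm else None,
            "crf": self.crf.to_dict() if self.crf else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinkagePipeline":
        p = cls(
            model=d["model"],
            figure_model=d.get("figure_model", "mixture"),
            background_model=d.get("background_model", "fixed_size"),
            score_source=d.get("score_source", "z"),
            hmm_start=d.get("hmm_start", "learned"),
            d_max=int(d.get("d_max", 2)),
            l2=float(d.get("l2", 1e-2)),
            tokenizer=TokenizerConfig.from_dict(d.get("tokenizer", {})),
        )
        if d.get("lm_config"):
            p.lm_config = LMConfig.from_dict(d["lm_config"])
        if d.get("dm"):
            p.dm = DistanceModel.from_dict(d["dm"])
        if d.get("hmm"):
            p.hmm = HMMModel.from_dict(d["hmm"])
        if d.get("crf"):
            p.crf = CRFModel.from_dict(d["crf"])
        return p

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "LinkagePipeline":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
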