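"""Language models: distributions, scoring, fitting, baseline."""

import math

import numpy as np
import pytest

from figlink import (
    Article,
    Figure,
    LMConfig,
    TermVector,
    background_prob,
    figure_term_prob,
    fit_lm,
    lm_score,
    max_f1,
    score_article,
    sentence_vector,
    tfidf_baseline_score,
)
from figlink.lm import BackgroundModel, lambda_grid, prepare_articles, simplex_grid, v_grid
from figlink.synthetic import GeneratorConfig, generate_corpus


def tv(**counts):
    return TermVector(dict(counts))


class TestFigureTermProb:
    def test_caption_only_frequency(self):
        p = figure_term_prob(tv(x=2, y=1), tv(), "caption_only")
        assert p == {"x": pytest.approx(2 / 3), "y": pytest.approx(1 / 3)}

    def test_mixture_degenerates_to_caption(self):
        cap, ref = tv(a=1), tv(b=3)
        assert figure_term_prob(cap, ref, "mixture", beta=1.0) == figure_term_prob(
            cap, ref, "caption_only"
        )

    def test_pooled(self):
        # caption {a:1} pooled with refs {a:1, b:2}: counts {a:2, b:2} of 4
        p = figure_term_prob(tv(a=1), tv(a=1, b=2), "pooled")
        assert p == {"a": pytest.approx(2 / 4), "b": pytest.approx(2 / 4)}
        p2 = figure_term_prob(tv(a=1), tv(a=1, b=3), "pooled")
        assert p2 == {"a": pytest.approx(2 / 5), "b": pytest.approx(3 / 5)}

    def test_mixture_weights(self):
        p = figure_term_prob(tv(a=1), tv(b=1), "mixture", beta=0.25)
        assert p == {"a": pytest.approx(0.25), "b": pytest.approx(0.75)}

    def test_empty_source_falls_back(self):
        p = figure_term_prob(tv(), tv(b=2), "caption_only")
        assert p == {"b": 1.0}
        assert figure_term_prob(tv(), tv(), "mixture", beta=0.5) == {}

    def test_probabilities_sum_to_one(self):
        for model in ("caption_only", "referencing_only", "pooled"):
            p = figure_term_prob(tv(a=2, b=1), tv(b=4, c=1), model)
            assert sum(p.values()) == pytest.approx(1.0)


class TestBackgroundProb:
    def article(self):
        return Article("a", ["a a a b"], [Figure("", [])])

    def test_variable_size_add_one(self):
        bg = background_prob(self.article(), "variable_size")
        assert bg.prob("a") == pytest.approx(4 / 6)
        assert bg.prob("b") == pytest.approx(2 / 6)
        assert bg.prob("zz") == 0.0

    def test_fixed_size(self):
        bg = background_prob(self.article(), "fixed_size", V=10)
        assert bg.prob("a") == pytest.approx(4 / 14)
        assert bg.prob("b") == pytest.approx(2 / 14)
        assert bg.prob("zz") == pytest.approx(1 / 14)
        # mass over the implicit V-term vocabulary sums to 1
        total = bg.prob("a") + bg.prob("b") + (10 - 2) * bg.unseen
        assert total == pytest.approx(1.0)

    def test_fixed_size_requires_large_enough_V(self):
        with pytest.raises(ValueError, match="V=1"):
            background_prob(self.article(), "fixed_size", V=1)

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError, match="empty term pool"):
            background_prob(Article("e", ["..."], [Figure("!!", [])]), "variable_size")


class TestLmScore:
    def test_lambda_one_scores_zero(self):
        bg = BackgroundModel({"q": 0.1}, 0.0, 10, 1)
        assert lm_score(sentence_vector("q"), {"q": 0.5}, bg, 1.0) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        bg = BackgroundModel({"q": 0.1}, 0.0, 10, 1)
        s = lm_score(sentence_vector("q"), {"q": 0.5}, bg, 0.5)
        assert s == pytest.approx(math.log(3.0))

    def test_empty_sentence(self):
        bg = BackgroundModel({"q": 0.1}, 0.0, 10, 1)
        assert lm_score(sentence_vector(""), {}, bg, 0.5) == 0.0

    def test_zero_background_guard(self):
        bg = BackgroundModel({"q": 0.1}, 0.0, N=10, V_d=1)
        s = lm_score(sentence_vector("novel"), {"novel": 0.5}, bg, 0.5)
        eps = 1.0 / (10 + 1 + 1)
        assert s == pytest.approx(math.log(0.5 + 0.5 * 0.5 / eps))

    def test_additive_over_disjoint_term_sets(self):
        bg = BackgroundModel({"a": 0.2, "b": 0.3, "c": 0.1}, 0.0, 10, 3)
        fig = {"a": 0.5, "c": 0.2}
        whole = lm_score(sentence_vector("a b c"), fig, bg, 0.4)
        parts = lm_score(sentence_vector("a"), fig, bg, 0.4) + lm_score(
            sentence_vector("b c"), fig, bg, 0.4
        )
        assert whole == pytest.approx(parts)


class TestScoreArticle:
    def test_matches_componentwise_reference(self, small_corpus):
        """The vectorized article scorer equals composing the dict-based ops."""
        art = small_corpus[0]
        cfg = LMConfig("mixture", "fixed_size", lam=0.6, beta=0.4, V=2000)
        S = score_article(art, cfg).values
        bg = background_prob(art, "fixed_size", V=2000)
        from figlink import figure_counts

        for j, sent in enumerate(art.sentences):
            sv = sentence_vector(sent)
            for k, fig in enumerate(art.figures):
                cap, ref = figure_counts(fig)
                fp = figure_term_prob(cap, ref, "mixture", beta=0.4)
                assert S[j, k] == pytest.approx(lm_score(sv, fp, bg, 0.6))

    def test_hand_computed_two_by_two(self):
        art = Article(
            "toy",
            ["x y", "y z"],
            [Figure("x x y", []), Figure("z z", [])],
            linkage=[[1, 0], [0, 1]],
        )
        cfg = LMConfig("caption_only", "variable_size", lam=0.5)
        S = score_article(art, cfg).values
        bg = background_prob(art, "variable_size")
        p1 = figure_term_prob(*__import__("figlink").figure_counts(art.figures[0]), "caption_only")
        expected_00 = sum(
            math.log(0.5 + 0.5 * p1.get(t, 0.0) / bg.prob(t)) for t in ("x", "y")
        )
        assert S[0, 0] == pytest.approx(expected_00)

    def test_duplicate_figures_give_identical_columns(self):
        art = Article(
            "dup", ["x y z"], [Figure("x y", ["z w"]), Figure("x y", ["z w"])]
        )
        cfg = LMConfig("pooled", "variable_size", lam=0.3)
        S = score_article(art, cfg).values
        assert S[0, 0] == pytest.approx(S[0, 1])

    def test_figure_permutation_permutes_columns(self, small_corpus):
        art = small_corpus[1]
        cfg = LMConfig("pooled", "variable_size", lam=0.5)
        S = score_article(art, cfg).values
        perm = Article(art.article_id, art.sentences, art.figures[::-1])
        S2 = score_article(perm, cfg).values
        np.testing.assert_allclose(S2, S[:, ::-1], rtol=1e-12)


class TestMaxF1:
    def brute(self, scores, labels):
        best = 0.0
        for th in np.unique(scores):
            pred = scores >= th
            tp = int((pred & (labels == 1)).sum())
            denom = pred.sum() + labels.sum()
            best = max(best, 2 * tp / denom if denom else 0.0)
        return best

    def test_matches_exhaustive_threshold_sweep(self, rng):
        for _ in range(30):
            scores = rng.choice([0.1, 0.5, 0.9, 1.3], size=12)
            labels = rng.integers(0, 2, size=12)
            if labels.sum() == 0:
                continue
            assert max_f1(scores, labels) == pytest.approx(self.brute(scores, labels))

    def test_perfect_ranking(self):
        assert max_f1(np.array([3.0, 2.0, 1.0]), np.array([1, 1, 0])) == 1.0


class TestFitLM:
    def test_grids_are_the_documented_sizes(self):
        assert len(lambda_grid()) == 99
        assert len(simplex_grid()) == 120
        lams = {round(l, 6) for l, _ in simplex_grid()}
        assert lams == {round(i / 14, 6) for i in range(15)}

    def test_fit_records_grid_sizes(self, train_corpus):
        cfg = fit_lm(train_corpus, "pooled", "variable_size")
        assert cfg.diagnostics["lambda_search_variable"]["grid_size"] == 99
        assert cfg.lam in np.round(lambda_grid(), 2)
        cfg.validate()

    def test_mixture_fit_uses_simplex(self, train_corpus):
        cfg = fit_lm(train_corpus, "mixture", "fixed_size")
        assert cfg.diagnostics["simplex_search_variable"]["grid_size"] == 120
        assert cfg.V is not None and cfg.beta is not None
        cfg.validate()

    def test_fixed_size_correlation_argmin_property(self, train_corpus):
        """|r(length, score)| at the chosen V never exceeds |r| at the
        grid's smallest vocabulary (the variable-size-like point)."""
        from figlink.lm import _length_score_correlation

        data = prepare_articles(train_corpus)
        cfg = fit_lm(train_corpus, "pooled", "fixed_size")
        corrs = cfg.diagnostics["v_search"]["abs_correlations"]
        grid = cfg.diagnostics["v_search"]["v_grid"]
        assert grid[0] == max(d.V_d for d in data)
        assert min(corrs) == corrs[grid.index(cfg.V)]

    def test_fit_requires_gold_links(self):
        art = Article("u", ["x"], [Figure("x")])
        with pytest.raises(ValueError, match="gold linkage"):
            fit_lm([art], "pooled", "variable_size")


class TestTfidfBaseline:
    def test_identical_text_scores_one(self):
        art = Article("t", ["alpha beta"], [Figure("alpha beta", [])])
        assert tfidf_baseline_score(art).values[0, 0] == pytest.approx(1.0)

    def test_disjoint_vocabulary_scores_zero(self):
        art = Article("t", ["alpha beta"], [Figure("gamma delta", [])])
        assert tfidf_baseline_score(art).values[0, 0] == 0.0

    def test_hand_computed_cosine(self):
        # docs: s1={a,b}, s2={c}, f1={a,c}; n_docs=3, smoothed idf
        art = Article("t", ["a b", "c"], [Figure("a c", [])])
        idf = {t: math.log(4 / 3) + 1 for t in ("a", "b", "c")}
        idf["b"] = math.log(4 / 2) + 1
        s1 = {"a": idf["a"], "b": idf["b"]}
        f1 = {"a": idf["a"], "c": idf["c"]}
        expected = (s1["a"] * f1["a"]) / (
            math.hypot(*s1.values()) * math.hypot(*f1.values())
        )
        assert tfidf_baseline_score(art).values[0, 0] == pytest.approx(expected)


def test_length_bias_smaller_for_fixed_size():
    """FixedSize backgrounds reduce the sentence-length/score correlation
    relative to VariableSize at the fitted V (qualitative bias check)."""
    from figlink.lm import _fit_simplex, _fit_V, _length_score_correlation

    arts = generate_corpus(GeneratorConfig(n_articles=15, seed=5))
    data = prepare_articles(arts)
    lam, beta, _ = _fit_simplex(data, "variable_size", None)
    r_var = abs(_length_score_correlation(data, "mixture", "variable_size", lam, beta, None))
    V, _ = _fit_V(data, "mixture", lam, beta)
    lam_f, beta_f, _ = _fit_simplex(data, "fixed_size", V)
    r_fix = abs(_length_score_correlation(data, "mixture", "fixed_size", lam_f, beta_f, V))
    assert r_fix < r_var
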