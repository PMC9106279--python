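import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from notepol.corpus_synth import generate_lda_corpus
from notepol.topics import (
    LdaModel,
    exclusivity,
    fit_lda,
    prevalence_effects,
    select_K,
    semantic_coherence,
    top_words,
)


def matched_tv(true_beta, est_beta):
    tv = 0.5 * np.abs(true_beta[:, None, :] - est_beta[None, :, :]).sum(axis=-1)
    r, c = linear_sum_assignment(tv)
    return tv[r, c].mean()


@pytest.fixture(scope="module")
def planted_corpus():
    return generate_lda_corpus(4, 120, 200, 25, 0.1, 0.01, seed=5)


@pytest.fixture(scope="module")
def planted_model(planted_corpus):
    docs, _, _ = planted_corpus
    return fit_lda(
        docs, 4, alpha=0.1, eta=0.01, n_iter=500, burn_in=250, thin=5, seed=5,
        vocabulary=list(range(120)),
    )


class TestFitLda:
    def test_rows_stochastic(self, planted_model):
        assert np.allclose(planted_model.beta_hat.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(planted_model.theta_hat.sum(axis=1), 1.0, atol=1e-9)

    def test_count_conservation(self, planted_model, planted_corpus):
        docs, _, _ = planted_corpus
        total = sum(len(d) for d in docs)
        assert planted_model.assignment_doc_topic.sum() == pytest.approx(total)
        assert planted_model.assignment_topic_word.sum() == pytest.approx(total)

    def test_deterministic_per_seed(self):
        docs, _, _ = generate_lda_corpus(2, 30, 30, 20, 0.1, 0.01, seed=2)
        a = fit_lda(docs, 2, n_iter=100, burn_in=50, thin=5, seed=3)
        b = fit_lda(docs, 2, n_iter=100, burn_in=50, thin=5, seed=3)
        assert np.array_equal(a.beta_hat, b.beta_hat)
        assert np.array_equal(a.theta_hat, b.theta_hat)

    def test_k1_closed_form(self):
        docs = [[0, 0, 1], [1, 2, 2, 2]]
        eta = 0.01
        m = fit_lda(docs, 1, alpha=0.1, eta=eta, n_iter=20, burn_in=10, thin=1, seed=0)
        counts = np.array([2.0, 2.0, 3.0])
        expected = (counts + eta) / (counts.sum() + 3 * eta)
        assert np.allclose(m.beta_hat[0], expected, atol=1e-12)

    def test_disjoint_vocabulary_separation(self):
        rng = np.random.default_rng(6)
        docs = []
        for _ in range(40):
            docs.append(list(rng.integers(0, 15, size=30)))
        for _ in range(40):
            docs.append(list(rng.integers(15, 30, size=30)))
        m = fit_lda(docs, 2, alpha=0.1, eta=0.01, n_iter=300, burn_in=150, thin=5, seed=6)
        true_beta = np.zeros((2, 30))
        true_beta[0, :15] = 1 / 15
        true_beta[1, 15:] = 1 / 15
        assert matched_tv(true_beta, m.beta_hat) < 0.1

    def test_parameter_recovery(self, planted_corpus, planted_model):
        _, beta, _ = planted_corpus
        assert matched_tv(beta, planted_model.beta_hat) < 0.15

    def test_string_tokens_supported(self):
        docs = [["a", "b", "a"], ["c", "c", "b"]]
        m = fit_lda(docs, 2, n_iter=20, burn_in=10, thin=1, seed=0)
        assert m.vocabulary == ["a", "b", "c"]

    def test_empty_doc_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_lda([[0, 1], []], 2, n_iter=10, burn_in=5, seed=0)

    def test_v_less_than_k_rejected(self):
        with pytest.raises(ValueError):
            fit_lda([[0], [1]], 5, n_iter=10, burn_in=5, seed=0)


class TestCoherence:
    def test_saturated_cooccurrence_near_zero(self):
        # every top word in every document: each pair adds log((D+1)/D)
        docs = [list(range(5)) for _ in range(20)]
        m = fit_lda(docs, 1, n_iter=20, burn_in=10, thin=1, seed=0)
        coh = semantic_coherence(m, docs, M=5)
        n_pairs = 10
        assert coh[0] == pytest.approx(n_pairs * np.log(21 / 20))

    def test_never_cooccurring_strongly_negative(self):
        # words 0..4 appear in disjoint documents
        docs = [[w] * 4 for w in range(5) for _ in range(4)]
        m = fit_lda(docs, 1, n_iter=20, burn_in=10, thin=1, seed=0)
        coh = semantic_coherence(m, docs, M=5)
        n_pairs = 10
        assert coh[0] == pytest.approx(n_pairs * np.log(1 / 4))

    def test_nonpositive(self, planted_model, planted_corpus):
        docs, _, _ = planted_corpus
        assert (semantic_coherence(m := planted_model, docs) <= 1e-12).all()

    def test_true_k_beats_overfit_k(self, planted_corpus):
        docs, _, _ = planted_corpus
        vocab = list(range(120))
        m4 = fit_lda(docs, 4, alpha=0.1, eta=0.01, n_iter=300, burn_in=150, thin=5, seed=2, vocabulary=vocab)
        m9 = fit_lda(docs, 9, alpha=0.1, eta=0.01, n_iter=300, burn_in=150, thin=5, seed=2, vocabulary=vocab)
        assert semantic_coherence(m4, docs).mean() > semantic_coherence(m9, docs).mean()

    def test_m_larger_than_vocab_rejected(self, planted_model, planted_corpus):
        docs, _, _ = planted_corpus
        with pytest.raises(ValueError):
            semantic_coherence(planted_model, docs, M=10_000)


class TestExclusivity:
    def _model(self, beta):
        K, V = beta.shape
        return LdaModel(K, beta, np.full((1, K), 1 / K), 0.1, 0.01, 0, 0, 1, 0, list(range(V)))

    def test_disjoint_topics_near_one(self):
        beta = np.zeros((2, 20))
        beta[0, :10] = 1 / 10
        beta[1, 10:] = 1 / 10
        exc = exclusivity(self._model(beta), M=5)
        assert (exc > 0.9).all()

    def test_duplicated_topics_half_share_bound(self):
        rng = np.random.default_rng(0)
        row = rng.dirichlet(np.ones(30))
        beta = np.vstack([row, row])
        exc = exclusivity(self._model(beta), M=5)
        # share = 0.5 for every word; weighted harmonic mean ~= 1/1.7
        assert np.allclose(exc, exc[0])
        assert 0.5 < exc[0] < 0.65

    def test_in_unit_interval(self, planted_model):
        exc = exclusivity(planted_model)
        assert ((exc > 0) & (exc <= 1)).all()

    def test_decreases_past_true_k(self, planted_corpus):
        docs, _, _ = planted_corpus
        vocab = list(range(120))
        m4 = fit_lda(docs, 4, alpha=0.1, eta=0.01, n_iter=300, burn_in=150, thin=5, seed=2, vocabulary=vocab)
        m9 = fit_lda(docs, 9, alpha=0.1, eta=0.01, n_iter=300, burn_in=150, thin=5, seed=2, vocabulary=vocab)
        assert exclusivity(m4).mean() > exclusivity(m9).mean()


class TestSelectK:
    def test_grid_of_one_returns_it(self, planted_corpus):
        docs, _, _ = planted_corpus
        diag = select_K(docs, [4], n_iter=60, burn_in=30, seed=0)
        assert diag.selected_K == 4

    def test_recovers_planted_k_within_one(self, planted_corpus):
        docs, _, _ = planted_corpus
        diag = select_K(docs, range(2, 7), n_iter=250, burn_in=120, seed=3)
        assert diag.selected_K in {3, 4, 5}
        assert set(diag.coherence) == set(diag.K_grid) == set(diag.exclusivity)

    def test_top_words_shape(self, planted_model):
        words = top_words(planted_model, M=7)
        assert len(words) == 4 and all(len(w) == 7 for w in words)


class TestPrevalenceEffects:
    def _theta(self, rng, D, K, tilt_topic=None, groups=None):
        alpha = np.full(K, 0.5)
        theta = np.empty((D, K))
        for d in range(D):
            a = alpha.copy()
            if tilt_topic is not None and groups[d] == "covid":
                a[tilt_topic] += 1.5
            theta[d] = rng.dirichlet(a)
        return theta

    def test_planted_group_effect_detected(self):
        rng = np.random.default_rng(4)
        D, K = 300, 4
        groups = np.where(rng.random(D) < 0.5, "covid", "non_covid")
        months = rng.integers(0, 6, size=D)
        theta = self._theta(rng, D, K, tilt_topic=0, groups=groups)
        eff = prevalence_effects(theta, groups, months, n_perm=199, seed=0)
        assert eff.group_p[0] < 0.05
        # contrast is labels[1] ("non_covid") minus labels[0] ("covid")
        assert eff.group_effect[0] < 0

    def test_correlated_topics_form_edge(self):
        rng = np.random.default_rng(8)
        D = 200
        base = rng.beta(2, 2, size=D) * 0.6
        theta = np.column_stack([base / 2, base / 2, 0.9 - base, np.full(D, 0.1)])
        theta /= theta.sum(axis=1, keepdims=True)
        groups = np.array(["covid", "non_covid"] * 100)
        months = np.tile(np.arange(4), 50)
        eff = prevalence_effects(theta, groups, months, n_perm=99, seed=1)
        pairs = {(i, j) for i, j, _ in eff.edges}
        assert (0, 1) in pairs
        assert np.allclose(np.diag(eff.correlation), 1.0)
        assert np.allclose(eff.correlation, eff.correlation.T)

    def test_single_group_skips_group_terms(self):
        rng = np.random.default_rng(2)
        theta = rng.dirichlet(np.ones(3), size=60)
        groups = np.array(["covid"] * 60)
        months = rng.integers(0, 4, size=60)
        eff = prevalence_effects(theta, groups, months, n_perm=49, seed=0)
        assert np.isnan(eff.group_effect).all()
        assert not np.isnan(eff.month_p).any()

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(10)
        ps = []
        for rep in range(8):
            D, K = 120, 4
            theta = rng.dirichlet(np.full(K, 0.3), size=D)
            groups = np.where(rng.random(D) < 0.5, "covid", "non_covid")
            months = rng.integers(0, 6, size=D)
            eff = prevalence_effects(theta, groups, months, n_perm=99, seed=rep)
            ps.extend(eff.group_p.tolist())
        ps = np.asarray(ps)
        assert 0.0 <= np.mean(ps < 0.05) <= 0.20  # loose sanity; exact calibration in acceptance

    def test_misaligned_covariates_rejected(self):
        with pytest.raises(ValueError):
            prevalence_effects(np.ones((10, 2)) / 2, ["covid"] * 9, list(range(10)))
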