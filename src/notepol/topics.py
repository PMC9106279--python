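"""LDA topic modeling by collapsed Gibbs sampling, with model selection and
post hoc covariate prevalence analysis.

The sampler is native (numba-compiled inner loop). Model selection scores a
grid of K by mean semantic coherence (document co-occurrence of top words)
and mean exclusivity (FREX-style), picking the K with the best rank-sum of
the two criteria while reporting the whole frontier for a human override.

Covariate analysis is deliberately post hoc: document-topic proportions are
regressed on group, month and their interaction, with permutation inference
(group labels permuted within month strata). A model with covariates inside
the prior could replace this estimator behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy import stats as sps

__all__ = [
    "LdaModel",
    "TopicDiagnostics",
    "PrevalenceEffects",
    "fit_lda",
    "semantic_coherence",
    "exclusivity",
    "select_K",
    "prevalence_effects",
    "top_words",
]


@dataclass
class LdaModel:
    K: int
    beta_hat: np.ndarray  # K x V posterior-mean topic-word rows
    theta_hat: np.ndarray  # D x K posterior-mean doc-topic rows
    alpha: float
    eta: float
    n_iter: int
    burn_in: int
    thin: int
    seed: int
    vocabulary: list  # index-aligned with beta_hat columns
    assignment_doc_topic: np.ndarray = field(repr=False, default=None)  # final ndk counts
    assignment_topic_word: np.ndarray = field(repr=False, default=None)  # final nkw counts

    @property
    def V(self) -> int:
        return self.beta_hat.shape[1]

    @property
    def D(self) -> int:
        return self.theta_hat.shape[0]


@njit(cache=True)
def _gibbs(tokens, doc_of, K, V, D, alpha, eta, n_iter, burn_in, thin, seed):
    np.random.seed(seed)
    N = tokens.shape[0]
    z = np.empty(N, np.int64)
    ndk = np.zeros((D, K), np.float64)
    nkw = np.zeros((K, V), np.float64)
    nk = np.zeros(K, np.float64)
    nd = np.zeros(D, np.float64)
    for i in range(N):
        k = np.random.randint(0, K)
        z[i] = k
        ndk[doc_of[i], k] += 1.0
        nkw[k, tokens[i]] += 1.0
        nk[k] += 1.0
        nd[doc_of[i]] += 1.0

    beta_sum = np.zeros((K, V), np.float64)
    theta_sum = np.zeros((D, K), np.float64)
    n_samples = 0
    cum = np.empty(K, np.float64)
    for it in range(n_iter):
        for i in range(N):
            d = doc_of[i]
            w = tokens[i]
            k = z[i]
            ndk[d, k] -= 1.0
            nkw[k, w] -= 1.0
            nk[k] -= 1.0
            tot = 0.0
            for kk in range(K):
                tot += (ndk[d, kk] + alpha) * (nkw[kk, w] + eta) / (nk[kk] + V * eta)
                cum[kk] = tot
            u = np.random.random() * tot
            knew = 0
            while knew < K - 1 and cum[knew] < u:
                knew += 1
            z[i] = knew
            ndk[d, knew] += 1.0
            nkw[knew, w] += 1.0
            nk[knew] += 1.0
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_samples += 1
            for k in range(K):
                denom = nk[k] + V * eta
                for w in range(V):
                    beta_sum[k, w] += (nkw[k, w] + eta) / denom
            for d in range(D):
                denom = nd[d] + K * alpha
                for k in range(K):
                    theta_sum[d, k] += (ndk[d, k] + alpha) / denom
    if n_samples == 0:
        n_samples = 1
        for k in range(K):
            denom = nk[k] + V * eta
            for w in range(V):
                beta_sum[k, w] += (nkw[k, w] + eta) / denom
        for d in range(D):
            denom = nd[d] + K * alpha
            for k in range(K):
                theta_sum[d, k] += (ndk[d, k] + alpha) / denom
    return beta_sum / n_samples, theta_sum / n_samples, ndk, nkw


def _encode_docs(docs: Sequence, vocabulary: list | None):
    """Flatten docs into (token_ids, doc_ids, vocabulary)."""
    first = docs[0][0] if len(docs) and len(docs[0]) else None
    if vocabulary is None:
        if first is not None and isinstance(first, (int, np.integer)):
            vmax = max(int(max(d)) for d in docs if len(d))
            vocabulary = list(range(vmax + 1))
            index = None
        else:
            vocabulary = sorted({t for d in docs for t in d})
            index = {t: i for i, t in enumerate(vocabulary)}
    else:
        index = None if (first is not None and isinstance(first, (int, np.integer))) else {
            t: i for i, t in enumerate(vocabulary)
        }
    tokens, doc_of = [], []
    for d, doc in enumerate(docs):
        if len(doc) == 0:
            raise ValueError(f"doc {d} is empty; every doc needs >= 1 token")
        for t in doc:
            tokens.append(int(t) if index is None else index[t])
            doc_of.append(d)
    return (
        np.asarray(tokens, dtype=np.int64),
        np.asarray(doc_of, dtype=np.int64),
        list(vocabulary),
    )


def fit_lda(
    docs: Sequence,
    K: int,
    alpha: float | None = None,
    eta: float = 0.01,
    n_iter: int = 1000,
    burn_in: int = 500,
    thin: int = 10,
    seed: int = 0,
    vocabulary: list | None = None,
) -> LdaModel:
    """Collapsed Gibbs LDA; posterior-mean estimates from thinned post-burn-in
    sweeps. Deterministic for a fixed seed. ``alpha`` defaults to 50/K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    tokens, doc_of, vocab = _encode_docs(docs, vocabulary)
    V, D = len(vocab), len(docs)
    if V == 0:
        raise ValueError("empty vocabulary")
    if V < K:
        raise ValueError(f"V={V} < K={K}")
    if alpha is None:
        alpha = 50.0 / K
    beta_hat, theta_hat, ndk, nkw = _gibbs(
        tokens, doc_of, K, V, D, float(alpha), float(eta), int(n_iter), int(burn_in), int(thin), int(seed)
    )
    return LdaModel(
        K=K,
        beta_hat=beta_hat,
        theta_hat=theta_hat,
        alpha=float(alpha),
        eta=float(eta),
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        vocabulary=vocab,
        assignment_doc_topic=ndk,
        assignment_topic_word=nkw,
    )


def top_words(model: LdaModel, M: int = 10) -> list:
    """Per topic, the M highest-probability words."""
    out = []
    for k in range(model.K):
        idx = np.argsort(model.beta_hat[k])[::-1][:M]
        out.append([model.vocabulary[i] for i in idx])
    return out


def semantic_coherence(model: LdaModel, docs: Sequence, M: int = 10) -> np.ndarray:
    """Document co-occurrence coherence of each topic's top-M words.

    For topic top words ordered by probability, sum over pairs i<j of
    log((D(w_i, w_j) + 1) / D(w_j)) with D(.) document frequencies.
    Always <= 0; higher (closer to 0) is better.
    """
    if M > model.V:
        raise ValueError(f"M={M} exceeds vocabulary size {model.V}")
    index = {t: i for i, t in enumerate(model.vocabulary)}
    D = len(docs)
    presence = np.zeros((D, model.V), dtype=bool)
    for d, doc in enumerate(docs):
        for t in doc:
            presence[d, int(t) if isinstance(t, (int, np.integer)) else index[t]] = True
    df = presence.sum(axis=0).astype(float)
    scores = np.zeros(model.K)
    for k in range(model.K):
        top = np.argsort(model.beta_hat[k])[::-1][:M]
        s = 0.0
        for a in range(M):
            for b in range(a + 1, M):
                co = float(np.sum(presence[:, top[a]] & presence[:, top[b]]))
                s += np.log((co + 1.0) / max(df[top[b]], 1.0))
        scores[k] = s
    return scores


def exclusivity(model: LdaModel, M: int = 10, frex_weight: float = 0.7) -> np.ndarray:
    """FREX-style exclusivity per topic, averaged over top-M words.

    Weighted harmonic mean of the word's exclusivity share
    beta[t,w] / sum_t' beta[t',w] and the within-topic frequency ECDF.
    In (0, 1]; higher is better.
    """
    beta = model.beta_hat
    share = beta / beta.sum(axis=0, keepdims=True)
    scores = np.zeros(model.K)
    for k in range(model.K):
        freq_ecdf = sps.rankdata(beta[k], method="average") / model.V
        top = np.argsort(beta[k])[::-1][:M]
        frex = 1.0 / (frex_weight / share[k, top] + (1.0 - frex_weight) / freq_ecdf[top])
        scores[k] = float(frex.mean())
    return scores


@dataclass
class TopicDiagnostics:
    K_grid: list
    coherence: dict  # K -> mean coherence
    exclusivity: dict  # K -> mean exclusivity
    selected_K: int
    per_topic: dict = field(default_factory=dict)  # K -> (coherence array, exclusivity array)
    models: dict = field(default_factory=dict, repr=False)


def select_K(
    docs: Sequence,
    K_grid: Sequence,
    M: int = 10,
    seed: int = 0,
    alpha: float | None = None,
    eta: float = 0.01,
    n_iter: int = 400,
    burn_in: int = 200,
    thin: int = 5,
    keep_models: bool = True,
) -> TopicDiagnostics:
    """Fit each K on a per-K seed schedule and pick the best rank-sum of
    (coherence rank + exclusivity rank); full frontier kept for override."""
    K_grid = sorted(set(int(k) for k in K_grid))
    if not K_grid:
        raise ValueError("empty K grid")
    coh, exc, per_topic, models = {}, {}, {}, {}
    for K in K_grid:
        m = fit_lda(docs, K, alpha=alpha, eta=eta, n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed + K)
        c = semantic_coherence(m, docs, M=min(M, m.V))
        e = exclusivity(m, M=min(M, m.V))
        coh[K], exc[K] = float(c.mean()), float(e.mean())
        per_topic[K] = (c, e)
        if keep_models:
            models[K] = m
    cvals = np.array([coh[K] for K in K_grid])
    evals = np.array([exc[K] for K in K_grid])
    ranks = sps.rankdata(cvals) + sps.rankdata(evals)  # higher value -> higher rank
    selected = K_grid[int(np.argmax(ranks))]
    return TopicDiagnostics(K_grid, coh, exc, selected, per_topic, models)


@dataclass
class PrevalenceEffects:
    topics: int
    group_labels: list  # [reference, contrast]
    group_effect: np.ndarray  # contrast minus reference mean theta
    group_p: np.ndarray
    month_trend: np.ndarray  # OLS slope on month index
    month_p: np.ndarray
    interaction: np.ndarray  # OLS group x month coefficient
    interaction_p: np.ndarray
    correlation: np.ndarray  # K x K Pearson over theta columns
    edges: list  # (i, j, r) with |r| >= threshold, i < j
    threshold: float
    n_perm: int


def _ols_coefs(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, Y, rcond=None)[0]


def prevalence_effects(
    theta: np.ndarray,
    groups: Sequence,
    months: Sequence,
    n_perm: int = 999,
    seed: int = 0,
    threshold: float = 0.3,
) -> PrevalenceEffects:
    """Post hoc covariate analysis of document-topic proportions.

    Per topic: group effect = difference in mean theta (contrast minus
    reference group, labels sorted); month trend and group x month
    interaction from least squares on (1, g, m, g*m) with centered month.
    P-values are permutation-based: group labels permuted within month
    strata for group and interaction effects; month labels permuted within
    groups for the month trend. Correlation network over theta columns.
    """
    theta = np.asarray(theta, dtype=float)
    D, K = theta.shape
    groups = np.asarray(groups)
    months = np.asarray(months, dtype=float)
    if groups.shape[0] != D or months.shape[0] != D:
        raise ValueError("covariates must align with theta rows")
    labels = sorted(set(groups.tolist()))
    rng = np.random.default_rng(seed)

    single_group = len(labels) < 2
    g = None if single_group else (groups == labels[1]).astype(float)
    mc = months - months.mean()

    def fit_stats(gv):
        if gv is None:
            X = np.column_stack([np.ones(D), mc])
            coefs = _ols_coefs(X, theta)
            return None, coefs[1], None
        X = np.column_stack([np.ones(D), gv, mc, gv * mc])
        coefs = _ols_coefs(X, theta)
        diff = theta[gv == 1].mean(axis=0) - theta[gv == 0].mean(axis=0)
        return diff, coefs[2], coefs[3]

    obs_diff, obs_month, obs_inter = fit_stats(g)

    month_vals = np.unique(months)
    strata = [np.where(months == m)[0] for m in month_vals]

    if single_group:
        group_p = inter_p = np.full(K, np.nan)
        group_effect = inter = np.full(K, np.nan)
    else:
        group_effect, inter = obs_diff, obs_inter
        hits_g = np.zeros(K)
        hits_i = np.zeros(K)
        for _ in range(n_perm):
            gp = g.copy()
            for idx in strata:
                gp[idx] = rng.permutation(gp[idx])
            if gp.std() == 0:  # degenerate permutation
                continue
            d, _, it = fit_stats(gp)
            hits_g += np.abs(d) >= np.abs(obs_diff) - 1e-15
            hits_i += np.abs(it) >= np.abs(obs_inter) - 1e-15
        group_p = (1.0 + hits_g) / (1.0 + n_perm)
        inter_p = (1.0 + hits_i) / (1.0 + n_perm)

    # month trend null: months permuted within group strata
    gstrata = (
        [np.arange(D)] if single_group else [np.where(groups == lab)[0] for lab in labels]
    )
    hits_m = np.zeros(K)
    for _ in range(n_perm):
        mp = months.copy()
        for idx in gstrata:
            mp[idx] = rng.permutation(mp[idx])
        mpc = mp - mp.mean()
        if g is None:
            X = np.column_stack([np.ones(D), mpc])
            slope = _ols_coefs(X, theta)[1]
        else:
            X = np.column_stack([np.ones(D), g, mpc, g * mpc])
            slope = _ols_coefs(X, theta)[2]
        hits_m += np.abs(slope) >= np.abs(obs_month) - 1e-15
    month_p = (1.0 + hits_m) / (1.0 + n_perm)

    corr = np.corrcoef(theta.T)
    edges = [
        (i, j, float(corr[i, j]))
        for i in range(K)
        for j in range(i + 1, K)
        if abs(corr[i, j]) >= threshold
    ]
    return PrevalenceEffects(
        topics=K,
        group_labels=labels,
        group_effect=group_effect,
        group_p=group_p,
        month_trend=obs_month,
        month_p=month_p,
        interaction=inter,
        interaction_p=inter_p,
        correlation=corr,
        edges=edges,
        threshold=threshold,
        n_perm=n_perm,
    )
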