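import math
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from notepol.corpus_synth import build_polarity_fixtures
from notepol.lexicons import BinaryLexicon, ValenceShifterLexicon
from notepol.polarity import (
    PolarityConfig,
    compare_groups,
    fourier_trend,
    lilliefors,
    mann_whitney_u,
    note_polarity,
    score_sentence,
)

BIN = BinaryLexicon({"contento": 1, "estable": 1, "triste": -1, "grave": -1})
SHIFT = ValenceShifterLexicon(
    {"no": "negator", "nunca": "negator", "muy": "amplifier", "poco": "deamplifier"}
)
CFG = PolarityConfig()


def delta(tokens, cfg=CFG):
    return score_sentence(tokens, BIN, SHIFT, cfg).delta


class TestScoreSentence:
    def test_plain_positive_anchor(self):
        assert delta(["paciente", "estable"]) == pytest.approx(1 / math.sqrt(2))

    def test_negated_positive_anchor(self):
        assert delta(["no", "contento"]) == pytest.approx(-1 / math.sqrt(2))

    def test_no_matches_gives_zero(self):
        assert delta(["sin", "novedades", "hoy"]) == 0.0

    def test_amplified_anchor(self):
        assert delta(["muy", "contento"]) == pytest.approx(1.8 / math.sqrt(2))

    def test_deamplified_anchor(self):
        assert delta(["poco", "contento"]) == pytest.approx((1 - 0.8) / math.sqrt(2))

    def test_deamplifier_floor(self):
        # three deamplifiers: c*(0-3) = -2.4 floored at -1 -> weight 0
        assert delta(["poco", "poco", "poco", "contento"]) == 0.0

    def test_double_negation_restores_sign(self):
        one = delta(["no", "contento", "x"])
        two = delta(["no", "nunca", "contento"])
        assert one < 0 < two

    def test_comma_truncates_left_context(self):
        with_comma = delta(["no", ",", "contento"])
        without = delta(["no", "contento", "x"])
        assert with_comma > 0 > without

    def test_comma_excluded_from_word_count(self):
        assert delta(["contento", ","]) == pytest.approx(1.0)
        sp = score_sentence(["contento", ","], BIN, SHIFT)
        assert sp.n_words == 1

    def test_negator_outside_window_ignored(self):
        toks = ["no", "a", "b", "c", "d", "contento"]  # negator 5 left of anchor
        assert delta(toks) > 0

    def test_shifter_after_anchor_counts(self):
        assert delta(["contento", "muy"]) == pytest.approx(1.8 / math.sqrt(2))

    def test_right_window_limit(self):
        toks = ["contento", "a", "b", "muy"]  # amplifier 3 right of anchor
        assert delta(toks) == pytest.approx(1 / math.sqrt(4))

    def test_traces_account_for_cluster(self):
        sp = score_sentence(["muy", "no", "contento", "x"], BIN, SHIFT)
        (tr,) = sp.traces
        assert tr.anchor_index == 2
        assert tr.n_amplifiers == 1 and tr.n_negators == 1 and tr.n_neutral == 1
        assert tr.anchor_index not in tr.cluster_indices
        assert tr.n_negators + tr.n_amplifiers + tr.n_deamplifiers + tr.n_neutral == len(
            tr.cluster_indices
        )
        assert sp.delta == pytest.approx(sum(t.weighted_value for t in sp.traces) / math.sqrt(4))

    def test_overlapping_clusters_scored_independently(self):
        sp = score_sentence(["contento", "triste"], BIN, SHIFT)
        assert len(sp.traces) == 2
        assert sp.delta == pytest.approx(0.0)

    def test_negated_amp_flip_variant(self):
        cfg = PolarityConfig(negated_amp_flip=True)
        # "no muy contento": amplifier re-classified as deamplifier
        assert delta(["no", "muy", "contento"], cfg) == pytest.approx(-(1 - 0.8) / math.sqrt(3))
        assert delta(["no", "muy", "contento"]) == pytest.approx(-1.8 / math.sqrt(3))

    def test_empty_sentence_raises(self):
        with pytest.raises(ValueError):
            score_sentence([], BIN, SHIFT)

    def test_oracle_equivalence_on_grid(self, lexicons):
        for toks, expected in build_polarity_fixtures():
            got = score_sentence(toks, lexicons["binary"], lexicons["shifter"]).delta
            assert got == expected  # exact


class TestInvariants:
    def test_sign_equivariance(self):
        flipped = BinaryLexicon({t: -v for t, v in BIN.entries.items()})
        toks = ["no", "muy", "contento", "y", "poco", "grave"]
        a = score_sentence(toks, BIN, SHIFT).delta
        b = score_sentence(toks, flipped, SHIFT).delta
        assert a == -b

    def test_negator_parity_flip(self):
        base = ["x", "contento", "y"]
        one = ["no", "contento", "y"]
        two_shift = ValenceShifterLexicon({**SHIFT.entries, "x": "negator", "y": "negator"})
        w0 = score_sentence(base, BIN, SHIFT).traces[0].weighted_value
        w1 = score_sentence(one, BIN, SHIFT).traces[0].weighted_value
        w2 = score_sentence(base, BIN, two_shift).traces[0].weighted_value
        assert w1 == -w0 and w2 == w0

    def test_sqrt_n_padding_law(self):
        toks = ["muy", "contento", "x"]
        base = delta(toks)
        for k in (1, 3, 7):
            padded = delta(toks + [f"pad{i}" for i in range(k)])
            n = 3
            assert padded == pytest.approx(base * math.sqrt(n / (n + k)))

    def test_amplifier_monotone_deamplifier_floor(self):
        d0 = delta(["contento", "x"])
        d1 = delta(["muy", "contento"])
        d2 = delta(["poco", "contento"])
        assert d1 > d0 > d2 >= 0.0


class TestNotePolarity:
    def test_single_sentence(self):
        sp = score_sentence(["contento"], BIN, SHIFT)
        assert note_polarity([sp]) == sp.delta

    def test_symmetric_sentences_cancel(self):
        a = score_sentence(["contento"], BIN, SHIFT)
        b = score_sentence(["triste"], BIN, SHIFT)
        assert note_polarity([a, b]) == pytest.approx(0.0)

    def test_mean_of_three(self, lexicons):
        fx = build_polarity_fixtures()[:3]
        sps_ = [score_sentence(t, lexicons["binary"], lexicons["shifter"]) for t, _ in fx]
        assert note_polarity(sps_) == pytest.approx(np.mean([d for _, d in fx]))


class TestFourierTrend:
    def test_constant_series_unchanged(self):
        x = np.full(12, 3.2)
        assert np.allclose(fourier_trend(x, 2), x, atol=1e-12)

    def test_cosine_eigenfunction(self):
        t = np.arange(32)
        x = np.cos(2 * np.pi * t / 32)
        assert np.allclose(fourier_trend(x, 1), x, atol=1e-9)

    def test_high_frequency_removed(self):
        t = np.arange(32)
        x = np.cos(2 * np.pi * 10 * t / 32)
        assert np.abs(fourier_trend(x, 2)).max() < 1e-9

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(64)
        assert fourier_trend(x, 3).var() < x.var()

    def test_k_low_too_large_warns_and_passes_through(self):
        x = np.arange(6.0)
        with pytest.warns(UserWarning):
            out = fourier_trend(x, 3)
        assert np.array_equal(out, x)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            fourier_trend([1.0, 2.0], 1)


class TestGroupComparison:
    def test_identical_samples_z_zero_p_one(self):
        x = np.arange(20.0)
        res = compare_groups({"a": x, "b": x.copy()})
        assert res["mann_whitney"]["Z"] == pytest.approx(0.0)
        assert res["mann_whitney"]["p"] == pytest.approx(1.0)

    def test_separated_samples_u_zero(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0.0

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.standard_normal(30)
            y = rng.standard_normal(25) + 0.3
            ours = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert ours["U1"] == pytest.approx(float(ref.statistic))
            assert ours["p"] == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_lilliefors_rejects_uniform(self):
        rng = np.random.default_rng(2)
        res = lilliefors(rng.uniform(size=200), seed=1)
        assert res["p"] < 0.01

    def test_lilliefors_degenerate_flagged(self):
        res = lilliefors(np.ones(10), seed=1)
        assert res["flag"] is not None and res["p"] is None

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 8"):
            compare_groups({"a": np.arange(5.0), "b": np.arange(20.0)})

    def test_report_summary_fields(self):
        rng = np.random.default_rng(3)
        res = compare_groups({"a": rng.normal(size=40), "b": rng.normal(0.5, size=35)})
        assert set(res["summary"]) == {"a", "b"}
        for s in res["summary"].values():
            assert {"n", "mean", "sd"} <= set(s)
        assert 0 <= res["mann_whitney"]["p"] <= 1
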