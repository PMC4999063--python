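import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from pprbind.motifs import RNATranscript
from pprbind.stats import (
    BackgroundDistribution,
    bh_adjust,
    build_background,
    false_positive_rate,
    loo_evaluate,
    permute_transcripts,
    pvalue,
    roc_auc,
)
from pprbind.synthetic import gen_pair_sequence, gen_training_corpus, gen_transcript


@pytest.fixture(scope="module")
def background():
    rng = np.random.default_rng(0)
    scores = rng.normal(-9.0, 1.0, size=5000)
    return BackgroundDistribution.from_scores(scores)


class TestBackground:
    def test_count_identity_single_transcript(self, trained_model):
        rng = np.random.default_rng(1)
        pairs = gen_pair_sequence(rng, 12, frac_specific=1.0)
        db = [gen_transcript(rng, 50, "t0")]
        bg = build_background(trained_model, pairs, db, include_targets=False)
        assert bg.count == 50 - 12 + 1 == 39

    def test_count_identity_with_targets(self, trained_model):
        rng = np.random.default_rng(2)
        pairs = gen_pair_sequence(rng, 10, frac_specific=1.0)
        db = [gen_transcript(rng, n, f"t{n}") for n in (40, 60)]
        target = [gen_transcript(rng, 25, "target")]
        bg = build_background(trained_model, pairs, db, include_targets=True, targets=target)
        assert bg.count == (40 - 9) + (60 - 9) + (25 - 9)

    def test_moment_fit(self, trained_model):
        rng = np.random.default_rng(3)
        pairs = gen_pair_sequence(rng, 12, frac_specific=1.0)
        db = [gen_transcript(rng, 200, f"t{k}") for k in range(3)]
        bg = build_background(trained_model, pairs, db, include_targets=False)
        assert bg.mu == pytest.approx(np.mean(bg.scores))
        assert bg.sigma == pytest.approx(np.std(bg.scores, ddof=1))

    def test_all_short_transcripts_error(self, trained_model):
        pairs = gen_pair_sequence(np.random.default_rng(4), 12, frac_specific=1.0)
        with pytest.raises(ValueError, match="shorter"):
            build_background(
                trained_model, pairs, [RNATranscript(id="t", bases="ACGU")],
                include_targets=False,
            )

    def test_normal_tail_calibration(self, trained_model):
        # empirical exceedance of mu + 1.6449 sigma should sit near 5%
        rng = np.random.default_rng(5)
        pairs = gen_pair_sequence(rng, 12, frac_specific=1.0)
        db = [gen_transcript(rng, 500, f"t{k}") for k in range(200)]
        bg = build_background(trained_model, pairs, db, include_targets=False)
        frac = np.mean(bg.scores > bg.mu + 1.6449 * bg.sigma)
        assert 0.03 <= frac <= 0.07


class TestPValue:
    def test_mean_score_gives_half(self, background):
        assert pvalue(background.mu, background) == pytest.approx(0.5)

    def test_95th_normal_quantile(self, background):
        p = pvalue(background.mu + 1.6449 * background.sigma, background)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_strictly_decreasing_in_score(self, background):
        scores = np.linspace(background.mu - 3, background.mu + 6, 40)
        ps = [pvalue(s, background) for s in scores]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_degenerate_background_rejected(self):
        bg = BackgroundDistribution(scores=np.ones(5), mu=1.0, sigma=0.0, count=5)
        with pytest.raises(ValueError, match="sigma"):
            pvalue(1.0, bg)


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_degenerate_families(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_statsmodels_and_invariants(self, ps):
        ours = bh_adjust(ps)
        theirs = multipletests(ps, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs, rel=1e-12)
        assert np.all(ours >= np.asarray(ps) - 1e-15)
        assert np.all(ours <= 1.0)


class TestDecoys:
    def test_multiset_and_length_preserved(self):
        db = [RNATranscript(id="a", bases="AUGC"), RNATranscript(id="b", bases="AAAAUUGGC")]
        decoys = permute_transcripts(db, seed=3)
        for src, d in zip(db, decoys):
            assert len(d.bases) == len(src.bases)
            assert sorted(d.bases) == sorted(src.bases)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        db = [gen_transcript(rng, 60, f"t{k}") for k in range(4)]
        assert [d.bases for d in permute_transcripts(db, 7)] == [
            d.bases for d in permute_transcripts(db, 7)
        ]
        other = permute_transcripts(db, 8)
        assert any(
            a.bases != b.bases for a, b in zip(permute_transcripts(db, 7), other)
        )


class TestFPR:
    def test_extremes_and_median(self):
        decoys = np.linspace(0, 1, 1001)
        assert false_positive_rate(2.0, decoys) == 0.0
        assert false_positive_rate(-1.0, decoys) == 1.0
        assert false_positive_rate(float(np.median(decoys)), decoys) == pytest.approx(
            0.5, abs=0.01
        )

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(1)
        decoys = rng.normal(size=500)
        grid = np.linspace(-3, 3, 50)
        rates = [false_positive_rate(s, decoys) for s in grid]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_empty_decoys_rejected(self):
        with pytest.raises(ValueError):
            false_positive_rate(0.0, [])


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([0.01, 0.02], [0.5, 0.9]) == 1.0

    def test_hand_worked_pairs(self):
        assert roc_auc([0.1, 0.4], [0.3, 0.5]) == pytest.approx(0.75)

    def test_null_expectation(self):
        rng = np.random.default_rng(0)
        x = rng.random(10_000)
        y = rng.random(10_000)
        assert 0.45 <= roc_auc(x, y) <= 0.55

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.random(50) * 0.5, rng.random(80)
        a = roc_auc(pos, neg)
        assert roc_auc(pos**2, neg**2) == pytest.approx(a)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        pos = rng.beta(1, 6, size=60)
        neg = rng.random(200)
        ours = roc_auc(pos, neg)
        # sklearn scores with larger = positive, so negate the p-values
        theirs = roc_auc_score([1] * 60 + [0] * 200, np.concatenate([-pos, -neg]))
        assert ours == pytest.approx(theirs)


class TestLOO:
    def test_record_per_event_and_planted_signal(self):
        rng = np.random.default_rng(17)
        corpus = gen_training_corpus(rng, n_events=30)
        db = [gen_transcript(rng, 400, f"bg{k}") for k in range(15)]
        records = loo_evaluate(corpus, db)
        assert len(records) == 30
        assert all(0 < r.pvalue <= 1 for r in records)
        assert all(r.padj >= r.pvalue - 1e-15 for r in records)
        # code-faithful events score far into the null's upper tail
        assert float(np.median([r.padj for r in records])) < 0.05

    def test_too_few_events_rejected(self):
        rng = np.random.default_rng(0)
        corpus = gen_training_corpus(rng, n_events=1)
        with pytest.raises(ValueError, match="at least 2"):
            loo_evaluate(corpus, [gen_transcript(rng, 100, "t")])
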