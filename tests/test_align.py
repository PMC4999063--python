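import math

import numpy as np
import pytest

from pprbind.align import (
    AlignedStep,
    _normalize,
    scan_contiguous,
    viterbi_topw,
)
from pprbind.hmm import RealizedTransitions, realize_transitions, train_model
from pprbind.motifs import RNATranscript
from pprbind.synthetic import (
    gen_cognate_site,
    gen_pair_sequence,
    gen_training_corpus,
    plant_site,
)

from oracle import enumerate_paths, random_parameters

_NT = {b: i for i, b in enumerate("ACGU")}


def _random_instance(rng, n, m):
    params, pairs = random_parameters(rng, m)
    bases = "".join(rng.choice(list("ACGU"), size=n))
    return params, pairs, RNATranscript(id="r", bases=bases)


def _emit_matrix(params, pairs):
    return np.array([params.emissions.log_row(t) for t in pairs.triples])


class TestViterbiAgainstEnumeration:
    """The DP must reproduce exhaustive path enumeration exactly."""

    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("n_extra", [0, 1, 2, 3, 5])
    def test_small_instances_match_oracle(self, m, n_extra):
        rng = np.random.default_rng(1000 * m + n_extra)
        n = m + n_extra
        for rep in range(8):
            params, pairs, rna = _random_instance(rng, n, m)
            rt = realize_transitions(params, n, m)
            emit = _emit_matrix(params, pairs)
            base = np.array([_NT[b] for b in rna.bases])
            oracle = enumerate_paths(rt, emit, base, n, m)
            w = 5
            results = viterbi_topw(params, pairs, rna, w=w)
            expect = [s for s, _ in oracle[:w]]
            got = [r.raw_log_score for r in results]
            assert got == expect  # exact, in log space

    def test_full_list_matches_oracle_count_and_scores(self):
        rng = np.random.default_rng(99)
        params, pairs, rna = _random_instance(rng, 6, 2)
        rt = realize_transitions(params, 6, 2)
        oracle = enumerate_paths(
            rt, _emit_matrix(params, pairs), np.array([_NT[b] for b in rna.bases]), 6, 2
        )
        results = viterbi_topw(params, pairs, rna, w=10_000)
        assert len(results) == len(oracle)
        assert [r.raw_log_score for r in results] == [s for s, _ in oracle]
        # decoded emitting paths match the enumerated ones rank for rank
        # (up to tie order, which only permutes equal scores)
        assert sorted("".join(s.state for s in r.steps) for r in results) == sorted(
            "".join(p) for _, p in oracle
        )


class TestDecodedPathProperties:
    def test_step_accounting_and_rank_monotonicity(self):
        rng = np.random.default_rng(5)
        for rep in range(20):
            m = int(rng.integers(1, 4))
            n = m + int(rng.integers(0, 6))
            params, pairs, rna = _random_instance(rng, n, m)
            results = viterbi_topw(params, pairs, rna, w=8)
            scores = [r.raw_log_score for r in results]
            assert scores == sorted(scores, reverse=True)
            paths = ["".join(s.state for s in r.steps) for r in results]
            assert len(set(paths)) == len(paths)
            for r in results:
                states = [s.state for s in r.steps]
                assert sum(s in ("M", "X", "D1", "D2") for s in states) == n
                assert sum(s in ("M", "Y") for s in states) == m
                assert r.path[0] == "start" and r.path[-1] == "end"
                n_mx = sum(s in ("M", "X") for s in states)
                assert r.span[1] - r.span[0] + 1 == n_mx
                assert math.isfinite(r.normalized_score)

    def test_gapless_model_decodes_contiguous_matches_only(self):
        rng = np.random.default_rng(11)
        corpus = gen_training_corpus(rng, n_events=40)
        model = train_model(corpus, gamma=0.0, eta=0.01)
        assert model.transitions.trained_rows["M"]["X"] == 0.0
        assert model.transitions.trained_rows["M"]["Y"] == 0.0
        pairs = gen_pair_sequence(rng, 10, frac_specific=1.0)
        site = gen_cognate_site(pairs, rng)
        rna, start = plant_site(site, 80, rng)
        for r in viterbi_topw(model, pairs, rna, w=5):
            states = [s.state for s in r.steps]
            assert "X" not in states and "Y" not in states
            m_pos = [s.rna_pos for s in r.steps if s.state == "M"]
            assert m_pos == list(range(m_pos[0], m_pos[0] + len(m_pos)))

    def test_single_all_match_path_when_rna_equals_pairs(self):
        rng = np.random.default_rng(13)
        corpus = gen_training_corpus(rng, n_events=40)
        model = train_model(corpus, gamma=0.0, eta=0.01)
        pairs = gen_pair_sequence(rng, 6, frac_specific=1.0)
        site = gen_cognate_site(pairs, rng)
        rna = RNATranscript(id="exact", bases=site)
        results = viterbi_topw(model, pairs, rna, w=5)
        assert len(results) == 1
        assert all(s.state == "M" for s in results[0].steps)
        rt = realize_transitions(model, rna.n, pairs.m)
        expected = (
            sum(
                model.emission_log_prob((t.aa6, t.aa1p), b, t.motif_type)
                for t, b in zip(pairs, site)
            )
            + (pairs.m - 1) * rt.log_prob("M", "M")
            + rt.log_prob("start", "M")
            + rt.log_prob("M", "end")
        )
        assert results[0].raw_log_score == pytest.approx(expected, abs=1e-9)


class TestNormalization:
    def test_hand_computed_normalized_score(self):
        # three matches entered with log T(D1,M) = -1.0, then T(M,M) = -0.5
        # twice, each emitting -1.5: (-6.5 - (-1.0)) / 3 = -1.8333...
        rt = RealizedTransitions(
            probs={
                ("D1", "M"): math.exp(-1.0),
                ("start", "M"): math.exp(-1.0),
                ("M", "M"): math.exp(-0.5),
            },
            q=math.exp(-1.0),
            n=3,
            m=3,
        )
        emit = np.full((3, 4), -1.5)
        base = np.zeros(3, dtype=int)
        steps = [AlignedStep(state="M", rna_pos=i + 1, pair_index=i + 1) for i in range(3)]
        assert _normalize(steps, rt, emit, base) == pytest.approx(-6.5 / 3 + 1.0 / 3)

    def test_single_match_normalized_is_emission_alone(self, trained_model):
        pairs = gen_pair_sequence(np.random.default_rng(3), 1, frac_specific=1.0)
        t = pairs[0]
        site = gen_cognate_site(pairs, np.random.default_rng(3))
        rna = RNATranscript(id="r", bases=site + "AAAA")
        best = viterbi_topw(trained_model, pairs, rna, w=1)[0]
        emitted = trained_model.emission_log_prob(
            (t.aa6, t.aa1p), rna.bases[best.span[0] - 1], t.motif_type
        )
        assert best.normalized_score == pytest.approx(emitted)

    def test_flank_invariance_across_transcript_lengths(self, trained_model):
        rng = np.random.default_rng(21)
        pairs = gen_pair_sequence(rng, 8, frac_specific=1.0)
        site = gen_cognate_site(pairs, rng)
        pad = "".join(rng.choice(list("ACGU"), size=500))
        short = RNATranscript(id="s", bases=pad[:20] + site + pad[:22])
        long = RNATranscript(id="l", bases=pad[:300] + site + pad[:192])
        s_short = viterbi_topw(trained_model, pairs, short, w=1)[0]
        s_long = viterbi_topw(trained_model, pairs, long, w=1)[0]
        assert s_short.span == (21, 20 + len(site))
        assert s_long.span == (301, 300 + len(site))
        assert s_short.normalized_score == s_long.normalized_score  # bit-identical


class TestScanContiguous:
    def test_offset_count(self, trained_model):
        rng = np.random.default_rng(2)
        pairs = gen_pair_sequence(rng, 12, frac_specific=1.0)
        rna = RNATranscript(id="r", bases="".join(rng.choice(list("ACGU"), size=100)))
        starts, scores = scan_contiguous(trained_model, pairs, rna)
        assert len(scores) == 89 and starts[0] == 1 and starts[-1] == 89
        site = gen_cognate_site(pairs, rng)
        one = scan_contiguous(trained_model, pairs, RNATranscript(id="x", bases=site))
        assert len(one[1]) == 1

    def test_argmax_matches_viterbi_top1_for_gapless_model(self):
        rng = np.random.default_rng(31)
        corpus = gen_training_corpus(rng, n_events=40)
        model = train_model(corpus, gamma=0.0, eta=0.01)
        pairs = gen_pair_sequence(rng, 10, frac_specific=1.0)
        site = gen_cognate_site(pairs, rng)
        rna, start = plant_site(site, 200, rng)
        starts, scores = scan_contiguous(model, pairs, rna)
        best = viterbi_topw(model, pairs, rna, w=1)[0]
        k = int(np.argmax(scores))
        assert starts[k] == best.span[0] == start
        assert scores[k] == pytest.approx(best.normalized_score, abs=1e-9)

    def test_rna_shorter_than_pairs_rejected(self, trained_model):
        pairs = gen_pair_sequence(np.random.default_rng(0), 12, frac_specific=1.0)
        with pytest.raises(ValueError, match="must be >="):
            scan_contiguous(trained_model, pairs, RNATranscript(id="r", bases="ACGUA"))
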