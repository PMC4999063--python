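import numpy as np
import pytest

from pprbind.hmm import AlignmentStep, TrainingCorpus, TrainingEvent


def make_event(event_id, pairs, site, flank5="", flank3=""):
    """Build a gapless training event from (aa6, aa1p, type) triples, the
    contacted site, and optional flanking bases."""
    steps = [AlignmentStep(state="D1", nucleotide=b) for b in flank5]
    steps += [
        AlignmentStep(state="M", aa6=a6, aa1p=a1, motif_type=mt, nucleotide=b)
        for (a6, a1, mt), b in zip(pairs, site)
    ]
    steps += [AlignmentStep(state="D2", nucleotide=b) for b in flank3]
    return TrainingEvent(event_id=event_id, steps=steps)


@pytest.fixture
def single_path_corpus():
    """One event with walk start, D1, M, M, D2, end."""
    return TrainingCorpus(
        events=[
            make_event(
                "ev1",
                [("T", "D", "P"), ("N", "N", "S")],
                "GC",
                flank5="A",
                flank3="U",
            )
        ]
    )


@pytest.fixture
def gapless_corpus():
    rng = np.random.default_rng(42)
    from pprbind.synthetic import gen_training_corpus

    return gen_training_corpus(rng, n_events=30)


@pytest.fixture
def trained_model(gapless_corpus):
    from pprbind.hmm import train_model

    return train_model(gapless_corpus)
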