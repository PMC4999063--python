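"""End-to-end synthetic benchmarks built from the library primitives.

These protocols tie the generators, the trained model, the scanner and the
statistics together the same way a study of a real transcriptome would:
train on an independent corpus, scan a database, rank placements, attach
BH-adjusted empirical-null p-values, and (for the decoy protocol) refer
scores to permuted transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import scan_contiguous
from .hmm import train_model
from .stats import (
    bh_adjust,
    build_background,
    false_positive_rate,
    permute_transcripts,
    pvalue,
)
from .synthetic import (
    gen_cognate_site,
    gen_pair_sequence,
    gen_training_corpus,
    gen_transcript,
    plant_site,
)


@dataclass
class PlantedSiteResult:
    """Outcome of one planted-site replicate."""

    top_transcript: str
    top_start: int
    true_transcript: str
    true_start: int
    top_padj: float
    top_is_planted: bool


def planted_site_replicate(
    seed: int,
    m: int = 12,
    n_transcripts: int = 20,
    transcript_length: int = 500,
    n_train_events: int = 200,
    gamma: float = 1.0,
    eta: float = 0.01,
) -> PlantedSiteResult:
    """Train on an independent synthetic corpus, plant one cognate site in a
    database of random transcripts, and test whether the planted placement
    is recovered as the top-ranked, BH-significant hit.

    The protein is fully coded (every pair carries a nucleotide preference),
    the planted transcript is chosen uniformly among the database, and the
    BH family is the per-transcript best placement (one hit per transcript).
    """
    rng = np.random.default_rng(seed)
    corpus = gen_training_corpus(rng, n_events=n_train_events)
    model = train_model(corpus, gamma=gamma, eta=eta)

    pairs = gen_pair_sequence(rng, m, frac_specific=1.0, protein_id="query")
    site = gen_cognate_site(pairs, rng)
    planted_idx = int(rng.integers(n_transcripts))
    transcripts = []
    true_start = None
    for t in range(n_transcripts):
        if t == planted_idx:
            tr, true_start = plant_site(site, transcript_length, rng, transcript_id=f"tx{t:02d}")
        else:
            tr = gen_transcript(rng, transcript_length, transcript_id=f"tx{t:02d}")
        transcripts.append(tr)

    bg = build_background(model, pairs, transcripts, include_targets=False)
    # one candidate hit per transcript: its best contiguous placement
    hits = []
    for tr in transcripts:
        starts, scores = scan_contiguous(model, pairs, tr)
        k = int(np.argmax(scores))
        hits.append((tr.id, int(starts[k]), float(scores[k])))
    pvals = [pvalue(score, bg) for _, _, score in hits]
    padj = bh_adjust(pvals)
    best = int(np.argmax([score for _, _, score in hits]))
    top_id, top_start, _ = hits[best]
    planted_id = transcripts[planted_idx].id
    return PlantedSiteResult(
        top_transcript=top_id,
        top_start=top_start,
        true_transcript=planted_id,
        true_start=int(true_start),
        top_padj=float(padj[best]),
        top_is_planted=(top_id == planted_id and top_start == true_start),
    )


def planted_site_recovery_rate(
    base_seed: int, n_replicates: int = 50, padj_threshold: float = 0.01, **kwargs
) -> tuple[float, list[PlantedSiteResult]]:
    """Fraction of seeded replicates in which the planted site is the
    top-ranked hit with BH-adjusted p below the threshold."""
    results = [
        planted_site_replicate(base_seed + r, **kwargs) for r in range(n_replicates)
    ]
    ok = sum(r.top_is_planted and r.top_padj < padj_threshold for r in results)
    return ok / n_replicates, results


@dataclass
class LOOBenchmark:
    """Summary of a leave-one-out benchmark on a synthetic corpus."""

    median_padj: float
    auc: float
    median_fpr: float
    n_events: int
    n_negatives: int


def synthetic_loo_benchmark(
    seed: int,
    n_events: int = 30,
    n_db_transcripts: int = 15,
    transcript_length: int = 400,
    gamma: float = 1.0,
    eta: float = 0.01,
) -> LOOBenchmark:
    """Leave-one-out evaluation on a synthetic corpus with a shared database.

    For each held-out event the model is trained on the rest, the event's
    pair sequence is aligned to its own RNA segment, and the normalized
    score is referred to the event's background (database + segment).  The
    per-event p-values (BH-adjusted as one family) are the positives; the
    pooled p-values of every background placement are the negatives for the
    ROC; the decoy FPR refers each event's score to a permuted database.
    """
    from scipy import stats as sps

    from .hmm import TrainingCorpus, event_pair_sequence, event_site
    from .motifs import RNATranscript

    rng = np.random.default_rng(seed)
    corpus = gen_training_corpus(rng, n_events=n_events)
    db = [
        gen_transcript(rng, transcript_length, transcript_id=f"bg{k:02d}")
        for k in range(n_db_transcripts)
    ]
    decoys = permute_transcripts(db, seed=seed + 1)

    from .align import viterbi_topw

    pvals, negatives, fprs = [], [], []
    for k, held in enumerate(corpus.events):
        rest = TrainingCorpus(events=corpus.events[:k] + corpus.events[k + 1 :])
        model = train_model(rest, gamma=gamma, eta=eta)
        pairs = event_pair_sequence(held)
        site = RNATranscript(id=f"{held.event_id}|site", bases=event_site(held))
        best = viterbi_topw(model, pairs, site, w=1)[0]
        bg = build_background(model, pairs, db, include_targets=True, targets=[site])
        pvals.append(pvalue(best.normalized_score, bg))
        negatives.append(sps.norm.sf(bg.scores, loc=bg.mu, scale=bg.sigma))
        decoy_scores = np.concatenate(
            [scan_contiguous(model, pairs, d)[1] for d in decoys if d.n >= pairs.m]
        )
        fprs.append(false_positive_rate(best.normalized_score, decoy_scores))

    padj = bh_adjust(pvals)
    negatives = np.concatenate(negatives)
    negatives = np.clip(negatives, np.finfo(float).tiny, 1.0)
    from .stats import roc_auc

    return LOOBenchmark(
        median_padj=float(np.median(padj)),
        auc=float(roc_auc(pvals, negatives)),
        median_fpr=float(np.median(fprs)),
        n_events=n_events,
        n_negatives=int(negatives.size),
    )


def decoy_fpr_experiment(
    seed: int,
    m: int = 12,
    n_transcripts: int = 20,
    transcript_length: int = 500,
    n_train_events: int = 200,
) -> float:
    """False positive rate of a planted cognate site against a decoy
    (per-transcript permuted) database."""
    rng = np.random.default_rng(seed)
    corpus = gen_training_corpus(rng, n_events=n_train_events)
    model = train_model(corpus)
    pairs = gen_pair_sequence(rng, m, frac_specific=1.0)
    site = gen_cognate_site(pairs, rng)
    transcripts = [
        gen_transcript(rng, transcript_length, transcript_id=f"tx{t:02d}")
        for t in range(n_transcripts)
    ]
    planted, start = plant_site(site, transcript_length, rng, transcript_id="target")
    _, target_scores = scan_contiguous(model, pairs, planted)
    target_score = float(target_scores[start - 1])

    decoys = permute_transcripts(transcripts, seed=seed + 1)
    decoy_scores = np.concatenate(
        [scan_contiguous(model, pairs, d)[1] for d in decoys]
    )
    return false_positive_rate(target_score, decoy_scores)
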