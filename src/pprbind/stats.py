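"""Background null model, p-values and evaluation protocols.

The null model for a pair sequence is the empirical distribution of the
normalized scores of *every* contiguous gapless placement of that sequence
across a transcript database; these scores are well approximated by a
normal, so a placement's p-value is the upper tail of the fitted
N(mu, sigma) at its score.  Multiple reported hits are adjusted with the
Benjamini-Hochberg step-up procedure.

Evaluation utilities mirror the standard benchmarking protocols for binding
site predictors: leave-one-out cross validation over a corpus of known
binding events, decoy (permuted-transcript) false positive rates, and a
rank-statistic ROC/AUC over pooled p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .align import scan_contiguous, viterbi_topw
from .hmm import TrainingCorpus, event_pair_sequence, event_site, train_model
from .motifs import PairSequence, RNATranscript

#: Smallest p-value ever reported; the true tail is never exactly zero.
P_FLOOR = float(np.nextafter(0, 1))


@dataclass
class BackgroundDistribution:
    """All contiguous-placement scores of one pair sequence vs a database."""

    scores: np.ndarray
    mu: float
    sigma: float
    count: int
    source: str = ""
    #: optional per-placement provenance: (transcript_id, starts, scores) chunks
    placements: list[tuple[str, np.ndarray, np.ndarray]] | None = None

    @classmethod
    def from_scores(
        cls, scores: np.ndarray, source: str = "", placements=None
    ) -> "BackgroundDistribution":
        scores = np.asarray(scores, dtype=float)
        if scores.size == 0:
            raise ValueError("empty background: no placements were scored")
        mu = float(scores.mean())
        sigma = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
        return cls(
            scores=scores,
            mu=mu,
            sigma=sigma,
            count=int(scores.size),
            source=source,
            placements=placements,
        )


@dataclass
class PredictionRecord:
    protein_id: str
    transcript_id: str
    span: tuple[int, int]
    normalized_score: float
    pvalue: float
    padj: float = field(default=float("nan"))


def build_background(
    params,
    pairs: PairSequence,
    database: list[RNATranscript],
    include_targets: bool = True,
    targets: list[RNATranscript] | None = None,
    source: str = "",
) -> BackgroundDistribution:
    """Score every gapless placement of ``pairs`` across the database.

    Target transcripts are included by default, matching the convention that
    the null contains the observed placement's own population.  Transcripts
    shorter than the pair sequence are skipped.
    """
    if not database:
        raise ValueError("background database is empty")
    pool = list(database)
    if include_targets and targets:
        pool += list(targets)
    chunks = []
    for tr in pool:
        if tr.n < pairs.m:
            continue
        starts, scores = scan_contiguous(params, pairs, tr)
        chunks.append((tr.id, starts, scores))
    if not chunks:
        raise ValueError(
            f"all transcripts are shorter than the pair sequence (m={pairs.m})"
        )
    return BackgroundDistribution.from_scores(
        np.concatenate([c[2] for c in chunks]), source=source, placements=chunks
    )


def pvalue(score: float, background: BackgroundDistribution) -> float:
    """One-sided upper-tail normal p-value of a normalized score."""
    if background.sigma <= 0:
        raise ValueError("degenerate background: sigma must be > 0")
    p = float(sps.norm.sf(score, loc=background.mu, scale=background.sigma))
    return max(p, P_FLOOR)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def permute_transcripts(
    database: list[RNATranscript], seed: int
) -> list[RNATranscript]:
    """Per-transcript random permutation: decoys preserve length and base
    composition of each source transcript.  Fully determined by ``seed``."""
    rng = np.random.default_rng(seed)
    decoys = []
    for tr in database:
        shuffled = "".join(rng.permutation(list(tr.bases)))
        decoys.append(RNATranscript(id=f"{tr.id}|decoy", bases=shuffled))
    return decoys


def false_positive_rate(score: float, decoy_scores) -> float:
    """Fraction of decoy placements scoring at least as high as ``score``."""
    d = np.asarray(decoy_scores, dtype=float)
    if d.size == 0:
        raise ValueError("decoy score set is empty")
    return float(np.count_nonzero(d >= score) / d.size)


def roc_auc(positive_pvalues, negative_pvalues) -> float:
    """Rank-statistic AUC with smaller p-value meaning a stronger prediction.

    Equals the probability that a random positive has a smaller p-value than
    a random negative, counting ties one half.
    """
    pos = np.asarray(positive_pvalues, dtype=float)
    neg = np.asarray(negative_pvalues, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    allp = np.concatenate([pos, neg])
    ranks = sps.rankdata(allp)  # ascending: small p -> small rank
    r_pos = ranks[: pos.size].sum()
    # U counts (pos < neg) pairs with ties at 1/2
    u = pos.size * neg.size + pos.size * (pos.size + 1) / 2 - r_pos
    return float(u / (pos.size * neg.size))


def loo_evaluate(
    corpus: TrainingCorpus,
    backgrounds: dict[str, list[RNATranscript]] | list[RNATranscript],
    gamma: float = 1.0,
    eta: float = 0.01,
    w: int = 1,
) -> list[PredictionRecord]:
    """Leave-one-out evaluation over a corpus of known binding events.

    For each event the model is re-trained on all other events, the held-out
    pair sequence is aligned to its own recorded RNA segment, the score is
    referred to the event's background database (which includes the target
    segment), and the per-event p-values are BH-adjusted as one family.

    ``backgrounds`` maps event_id to that event's transcript database, or is
    a single database shared by all events.
    """
    if len(corpus) < 2:
        raise ValueError("leave-one-out needs at least 2 events")
    records = []
    for k, held in enumerate(corpus.events):
        rest = TrainingCorpus(events=corpus.events[:k] + corpus.events[k + 1 :])
        model = train_model(rest, gamma=gamma, eta=eta)
        pairs = event_pair_sequence(held)
        site = RNATranscript(id=f"{held.event_id}|site", bases=event_site(held))
        hits = viterbi_topw(model, pairs, site, w=w)
        best = hits[0]
        db = backgrounds[held.event_id] if isinstance(backgrounds, dict) else backgrounds
        bg = build_background(
            model, pairs, db, include_targets=True, targets=[site], source=held.event_id
        )
        records.append(
            PredictionRecord(
                protein_id=held.event_id,
                transcript_id=site.id,
                span=best.span,
                normalized_score=best.normalized_score,
                pvalue=pvalue(best.normalized_score, bg),
            )
        )
    adj = bh_adjust([r.pvalue for r in records])
    for r, a in zip(records, adj):
        r.padj = float(a)
    return records
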