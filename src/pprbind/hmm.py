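"""Pair-HMM parameter estimation for PPR-RNA semi-global alignment.

The model has seven states.  ``M`` consumes one (aa6, aa1') pair and one RNA
base (a contact).  ``D1`` and ``D2`` consume RNA bases in the unaligned 5'
and 3' flanks, before the first and after the last contact respectively.
``X`` consumes an RNA base inside the contacted region (an internal gap on
the protein side, requiring a match on both sides); ``Y`` consumes a pair
without an RNA base (a gap on the RNA side).  ``start`` and ``end`` are
silent.

Transitions out of ``M``, ``X`` and ``Y`` are estimated from a corpus of
known binding events by pseudocounted relative frequency.  Transitions out
of ``start``, ``D1`` and ``D2`` depend on the lengths of the two sequences
being aligned and are realized per alignment problem: the flank-exit
probability is q = 1/((n-m)/2), i.e. a uniform prior over the expected flank
length, clamped into (0, 1].

Match emissions form a 400 x 4 x 3 table over (amino-acid pair, nucleotide,
motif type), normalized over the *whole* table so that rare pairs remain
informative.  Gap emissions are uniform (Q = 1/4 per base, O = 1/400 per
pair) so that alignments are discriminated by their contacts, not by their
gaps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motifs import AA_ALPHABET, MOTIF_TYPES, NT_ALPHABET, PairSequence, PairTriple

STATES = ("start", "D1", "D2", "M", "X", "Y", "end")

#: Legal transition structure of the seven-state model.
LEGAL_TRANSITIONS: dict[str, tuple[str, ...]] = {
    "start": ("M", "D1"),
    "D1": ("D1", "M"),
    "M": ("M", "X", "Y", "D2", "end"),
    "X": ("X", "M"),
    "Y": ("Y", "M"),
    "D2": ("D2", "end"),
}

#: States whose outgoing rows are estimated from the training corpus.
TRAINED_STATES = ("M", "X", "Y")

#: Log value substituted for zero-count emission cells so that decoding stays
#: defined; any path forced through such a cell scores far below every path
#: that avoids it.
EMISSION_LOG_FLOOR = -1e9

N_PAIRS = len(AA_ALPHABET) ** 2
N_CELLS = N_PAIRS * len(NT_ALPHABET) * len(MOTIF_TYPES)  # 4800

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_NT_INDEX = {b: i for i, b in enumerate(NT_ALPHABET)}
_TYPE_INDEX = {t: i for i, t in enumerate(MOTIF_TYPES)}

GAP = "-"
Q_GAP = 0.25  # uniform RNA-base emission in D1/D2/X
O_GAP = 1.0 / N_PAIRS  # uniform pair emission in Y


class CorpusError(ValueError):
    """A training event violates the state-walk or emission-field invariants."""


class DegenerateRowError(ValueError):
    """A reachable state has no outgoing probability mass; use a positive gamma."""


@dataclass(frozen=True)
class AlignmentStep:
    """One emitting step of a recorded binding event.

    M steps carry a pair and a nucleotide; D1/D2/X steps a nucleotide only;
    Y steps a pair only.  Unused fields hold '-'.
    """

    state: str
    aa6: str = GAP
    aa1p: str = GAP
    motif_type: str = GAP
    nucleotide: str = GAP


@dataclass
class TrainingEvent:
    event_id: str
    steps: list[AlignmentStep]


@dataclass
class TrainingCorpus:
    """A validated set of known PPR-RNA binding alignments."""

    events: list[TrainingEvent]

    def __post_init__(self):
        for ev in self.events:
            validate_event(ev)

    def __len__(self) -> int:
        return len(self.events)


def validate_event(event: TrainingEvent) -> None:
    if not event.steps:
        raise CorpusError(f"event {event.event_id!r} has no steps")
    walk = ["start"] + [s.state for s in event.steps] + ["end"]
    for a, b in zip(walk, walk[1:]):
        if a not in LEGAL_TRANSITIONS or b not in LEGAL_TRANSITIONS.get(a, ()):
            raise CorpusError(
                f"event {event.event_id!r}: illegal transition {a} -> {b}"
            )
    for i, s in enumerate(event.steps, start=1):
        has_pair = s.aa6 != GAP and s.aa1p != GAP and s.motif_type != GAP
        has_nt = s.nucleotide != GAP
        if s.state == "M" and not (has_pair and has_nt):
            raise CorpusError(
                f"event {event.event_id!r} step {i}: M step must carry both a pair and a nucleotide"
            )
        if s.state in ("D1", "D2", "X") and (has_pair or not has_nt):
            raise CorpusError(
                f"event {event.event_id!r} step {i}: {s.state} step must carry a nucleotide only"
            )
        if s.state == "Y" and (has_nt or not has_pair):
            raise CorpusError(
                f"event {event.event_id!r} step {i}: Y step must carry a pair only"
            )
        if has_nt and s.nucleotide not in NT_ALPHABET:
            raise CorpusError(
                f"event {event.event_id!r} step {i}: bad nucleotide {s.nucleotide!r}"
            )
        if has_pair and s.motif_type not in MOTIF_TYPES:
            raise CorpusError(
                f"event {event.event_id!r} step {i}: bad motif type {s.motif_type!r}"
            )


def event_site(event: TrainingEvent) -> str:
    """The RNA segment of an event: its consumed bases in order."""
    return "".join(s.nucleotide for s in event.steps if s.nucleotide != GAP)


def event_pair_sequence(event: TrainingEvent) -> PairSequence:
    """The (aa6, aa1', type) triples of an event, in order."""
    triples = [
        PairTriple(aa6=s.aa6, aa1p=s.aa1p, motif_type=s.motif_type)
        for s in event.steps
        if s.aa6 != GAP
    ]
    return PairSequence(triples=triples, protein_id=event.event_id)


def count_transitions(corpus: TrainingCorpus) -> dict[tuple[str, str], int]:
    """Count consecutive state pairs across all events, including the silent
    start -> first and last -> end transitions."""
    F: dict[tuple[str, str], int] = {}
    for ev in corpus.events:
        walk = ["start"] + [s.state for s in ev.steps] + ["end"]
        for a, b in zip(walk, walk[1:]):
            F[(a, b)] = F.get((a, b), 0) + 1
    return F


def pair_index(aa6: str, aa1p: str) -> int | None:
    """Row index of an amino-acid pair in the emission table, or None if a
    residue falls outside the 20-letter alphabet (X, B, Z, ...)."""
    i, j = _AA_INDEX.get(aa6), _AA_INDEX.get(aa1p)
    if i is None or j is None:
        return None
    return i * len(AA_ALPHABET) + j


def count_emissions(corpus: TrainingCorpus) -> np.ndarray:
    """Count match contacts into the (pair, nucleotide, motif-type) table.

    Only M steps contribute; gap steps carry no pair-nucleotide contact.
    """
    G = np.zeros((N_PAIRS, len(NT_ALPHABET), len(MOTIF_TYPES)))
    for ev in corpus.events:
        for i, s in enumerate(ev.steps, start=1):
            if s.state != "M":
                continue
            p = pair_index(s.aa6, s.aa1p)
            if p is None:
                raise CorpusError(
                    f"event {ev.event_id!r} step {i}: non-standard residue in "
                    f"pair ({s.aa6},{s.aa1p}); training pairs must use the "
                    "20-letter alphabet"
                )
            G[p, _NT_INDEX[s.nucleotide], _TYPE_INDEX[s.motif_type]] += 1
    return G


@dataclass
class TransitionModel:
    """Corpus-estimated rows of the transition matrix (states M, X, Y)."""

    F: dict[tuple[str, str], int]
    gamma: float
    trained_rows: dict[str, dict[str, float]]

    def prob(self, a: str, b: str) -> float:
        return self.trained_rows.get(a, {}).get(b, 0.0)


@dataclass
class EmissionModel:
    """Match-emission table plus the uniform gap emissions."""

    G: np.ndarray
    eta: float
    A: np.ndarray
    Q: float = Q_GAP
    O: float = O_GAP

    _logA: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        with np.errstate(divide="ignore"):
            logA = np.log(self.A)
        logA[self.A == 0.0] = EMISSION_LOG_FLOOR
        self._logA = logA

    def log_prob(self, aa6: str, aa1p: str, nucleotide: str, motif_type: str) -> float:
        """log A for a contact; pairs with non-standard residues emit the
        uniform cell value 1/4800, zero-probability cells the log floor."""
        p = pair_index(aa6, aa1p)
        if p is None:
            return -math.log(N_CELLS)
        return float(self._logA[p, _NT_INDEX[nucleotide], _TYPE_INDEX[motif_type]])

    def log_row(self, triple: PairTriple) -> np.ndarray:
        """Length-4 vector of log emission over A,C,G,U for one pair triple."""
        p = pair_index(triple.aa6, triple.aa1p)
        if p is None:
            return np.full(len(NT_ALPHABET), -math.log(N_CELLS))
        return self._logA[:, :, _TYPE_INDEX[triple.motif_type]][p].copy()


@dataclass
class PairHMMParameters:
    """Trained transition rows plus emission tables; realizes the scoring
    function used for alignment."""

    transitions: TransitionModel
    emissions: EmissionModel
    metadata: dict

    def emission_log_prob(
        self, pair: tuple[str, str], nucleotide: str, motif_type: str
    ) -> float:
        return self.emissions.log_prob(pair[0], pair[1], nucleotide, motif_type)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        doc = {
            "format_version": 1,
            "gamma": self.transitions.gamma,
            "eta": self.emissions.eta,
            "F": [[a, b, c] for (a, b), c in sorted(self.transitions.F.items())],
            "G": [
                [int(p), int(j), int(k), float(v)]
                for (p, j, k), v in np.ndenumerate(self.emissions.G)
                if v != 0
            ],
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PairHMMParameters":
        doc = json.loads(Path(path).read_text())
        if doc.get("format_version") != 1:
            raise ValueError(f"unsupported model format version in {path}")
        F = {(a, b): c for a, b, c in doc["F"]}
        G = np.zeros((N_PAIRS, len(NT_ALPHABET), len(MOTIF_TYPES)))
        for p, j, k, v in doc["G"]:
            G[p, j, k] = v
        return train_from_counts(
            F, G, gamma=doc["gamma"], eta=doc["eta"], metadata=doc.get("metadata", {})
        )


def _train_row(
    F: dict[tuple[str, str], int], alpha: str, gamma: float
) -> tuple[dict[str, float], float]:
    betas = LEGAL_TRANSITIONS[alpha]
    weights = {b: F.get((alpha, b), 0) + gamma for b in betas}
    total = sum(weights.values())
    if total == 0:
        return {b: 0.0 for b in betas}, 0.0
    return {b: w / total for b, w in weights.items()}, total


def train_from_counts(
    F: dict[tuple[str, str], int],
    G: np.ndarray,
    gamma: float = 1.0,
    eta: float = 0.01,
    metadata: dict | None = None,
) -> PairHMMParameters:
    """Turn transition/emission counts into a parameterized model.

    ``gamma`` is added to every legal transition leaving a trained state;
    ``eta`` to every emission cell.  The M row must receive positive mass.
    The X and Y rows may be all-zero only while they are unreachable (their
    incoming probability from M is zero) — the gapless-corpus case.
    """
    trained: dict[str, dict[str, float]] = {}
    row_m, total_m = _train_row(F, "M", gamma)
    if total_m == 0:
        raise DegenerateRowError(
            "state M has no observed transitions and gamma is 0; "
            "supply a non-empty corpus or a positive gamma"
        )
    trained["M"] = row_m
    for alpha in ("X", "Y"):
        row, total = _train_row(F, alpha, gamma)
        if total == 0 and row_m.get(alpha, 0.0) > 0:
            raise DegenerateRowError(
                f"state {alpha} is reachable (T(M,{alpha}) > 0) but has no "
                "outgoing mass; use a positive gamma"
            )
        trained[alpha] = row

    denom = float(G.sum() + eta * G.size)
    if denom == 0:
        raise DegenerateRowError(
            "emission table has no counts and eta is 0; "
            "supply M steps or a positive eta"
        )
    A = (G + eta) / denom
    return PairHMMParameters(
        transitions=TransitionModel(F=F, gamma=gamma, trained_rows=trained),
        emissions=EmissionModel(G=G, eta=eta, A=A),
        metadata=metadata or {},
    )


def train_model(
    corpus: TrainingCorpus,
    gamma: float = 1.0,
    eta: float = 0.01,
    metadata: dict | None = None,
) -> PairHMMParameters:
    """Estimate all model parameters from a corpus of binding events."""
    meta = {"n_events": len(corpus), "gamma": gamma, "eta": eta}
    meta.update(metadata or {})
    return train_from_counts(
        count_transitions(corpus), count_emissions(corpus), gamma=gamma, eta=eta, metadata=meta
    )


@dataclass
class RealizedTransitions:
    """The full transition matrix for one alignment problem of sizes (n, m).

    Flank rows use q = 1/((n-m)/2) clamped into (0, 1]; q = 1 means the RNA
    leaves no room for a flank.  Trained rows are copied unchanged.
    """

    probs: dict[tuple[str, str], float]
    q: float
    n: int
    m: int

    def prob(self, a: str, b: str) -> float:
        return self.probs.get((a, b), 0.0)

    def log_prob(self, a: str, b: str) -> float:
        p = self.probs.get((a, b), 0.0)
        return math.log(p) if p > 0 else -math.inf


def realize_transitions(
    params: PairHMMParameters, n: int, m: int
) -> RealizedTransitions:
    if n < m:
        raise ValueError(f"RNA length n={n} must be >= pair count m={m}")
    q = 1.0 if n - m <= 2 else 1.0 / ((n - m) / 2.0)
    probs: dict[tuple[str, str], float] = {}
    for a in TRAINED_STATES:
        for b, p in params.transitions.trained_rows[a].items():
            probs[(a, b)] = p
    probs[("start", "M")] = q
    probs[("start", "D1")] = 1.0 - q
    probs[("D1", "M")] = q
    probs[("D1", "D1")] = 1.0 - q
    probs[("D2", "end")] = q
    probs[("D2", "D2")] = 1.0 - q
    return RealizedTransitions(probs=probs, q=q, n=n, m=m)
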