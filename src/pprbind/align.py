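"""Semi-global k-best Viterbi decoding of a pair sequence against RNA.

The decoder finds the ``w`` top-scoring alignments of the (aa6, aa1') pair
sequence (length m) to an RNA sequence (length n >= m) under the seven-state
pair HMM.  Every cell of the dynamic program stores its ``w`` best partial
log scores with backpointers, which is sufficient for a global k-best list.
All computation is in natural-log space.

Scores are made comparable across transcripts by *normalization*: the sum of
the (transition + emission) log terms of every step entering M or X, minus
the flank-exit term log T(D1, M), divided by the number of M and X steps.
The flank terms and the length-dependent entry probability thus drop out, so
the same core alignment scores identically inside a 50-base or a 5000-base
transcript.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hmm import PairHMMParameters, RealizedTransitions, realize_transitions
from .motifs import NT_ALPHABET, PairSequence, RNATranscript

_NT_INDEX = {b: i for i, b in enumerate(NT_ALPHABET)}

# Deterministic tie-break order over predecessor states.
_STATE_ORDER = {"M": 0, "X": 1, "Y": 2, "D1": 3, "D2": 4, "start": 5}


class _Entry:
    """One ranked partial alignment ending at a DP cell."""

    __slots__ = ("score", "state", "i", "j", "prev")

    def __init__(self, score, state, i, j, prev):
        self.score = score
        self.state = state
        self.i = i
        self.j = j
        self.prev = prev


@dataclass
class AlignedStep:
    """One emitting step of a decoded alignment (1-based coordinates)."""

    state: str
    rna_pos: int | None  # None for Y steps
    pair_index: int | None  # None for D1/D2/X steps


@dataclass
class AlignmentResult:
    transcript_id: str
    path: list[str]  # start ... end
    steps: list[AlignedStep]
    raw_log_score: float
    normalized_score: float
    span: tuple[int, int]  # 1-based inclusive RNA coords of first/last M
    rank: int

    @property
    def path_string(self) -> str:
        """Compact emitting-state string, e.g. 'DDMMMMD' (D1/D2 both 'D')."""
        return "".join("D" if s.state in ("D1", "D2") else s.state for s in self.steps)


def _emission_matrix(params: PairHMMParameters, pairs: PairSequence) -> np.ndarray:
    """m x 4 matrix of log match-emission terms for this pair sequence."""
    return np.array([params.emissions.log_row(t) for t in pairs.triples])


def _top_w(candidates, w):
    """Sort candidates by score (desc) with the deterministic tie-break and
    keep the best w.  Candidates are (score, tiebreak, entry_args) tuples."""
    candidates.sort(key=lambda c: (-c[0], c[1]))
    return candidates[:w]


def viterbi_topw(
    params: PairHMMParameters,
    pairs: PairSequence,
    rna: RNATranscript,
    w: int = 1,
) -> list[AlignmentResult]:
    """Decode the ``w`` top-scoring semi-global alignments.

    Returns min(w, number of distinct positive-probability alignments)
    results sorted by raw log score, each with full traceback, raw and
    normalized scores.  Zero-probability transitions prune their paths;
    zero-probability emission cells contribute the log floor instead, so a
    path forced through one remains decodable but can never outrank a path
    that avoids it.
    """
    n, m = rna.n, pairs.m
    if m < 1:
        raise ValueError("pair sequence is empty")
    if n < m:
        raise ValueError(f"RNA length n={n} must be >= pair count m={m}")
    if w < 1:
        raise ValueError(f"w must be >= 1, got {w}")

    rt = realize_transitions(params, n, m)
    emit = _emission_matrix(params, pairs)
    base = np.fromiter((_NT_INDEX[b] for b in rna.bases), dtype=np.int64, count=n)

    lt = rt.log_prob
    lt_d1m = lt("D1", "M")
    lt_d1d1 = lt("D1", "D1")
    lt_mm, lt_xm, lt_ym = lt("M", "M"), lt("X", "M"), lt("Y", "M")
    lt_mx, lt_xx = lt("M", "X"), lt("X", "X")
    lt_my, lt_yy = lt("M", "Y"), lt("Y", "Y")
    lt_md2, lt_d2d2 = lt("M", "D2"), lt("D2", "D2")
    lt_mend, lt_d2end = lt("M", "end"), lt("D2", "end")
    log_q = math.log(params.emissions.Q)
    log_o = math.log(params.emissions.O)

    origin = _Entry(0.0, "start", 0, 0, None)

    # 5' flank chain (one path per length); chain[i] may be None when the
    # flank transition has probability 0 (the n - m <= 2 case).
    d1_chain: list[_Entry | None] = [origin]
    for i in range(1, n + 1):
        prev = d1_chain[i - 1]
        if prev is None or lt_d1d1 == -math.inf:
            d1_chain.append(None)
        else:
            d1_chain.append(_Entry(prev.score + lt_d1d1 + log_q, "D1", i, 0, prev))

    VM = [[[] for _ in range(m + 1)] for _ in range(n + 1)]
    VX = [[[] for _ in range(m + 1)] for _ in range(n + 1)]
    VY = [[[] for _ in range(m + 1)] for _ in range(n + 1)]

    def extend(cands, entries, ltrans, le, tag):
        if ltrans == -math.inf:
            return
        for r, e in enumerate(entries):
            s = e.score + ltrans + le
            if s == -math.inf:
                continue
            cands.append((s, (_STATE_ORDER[e.state], e.i, e.j, r), e))

    for i in range(1, n + 1):
        le_row = emit[:, base[i - 1]]
        for j in range(1, m + 1):
            # M consumes (rna i, pair j)
            cands = []
            le = float(le_row[j - 1])
            if j == 1:
                d1 = d1_chain[i - 1]
                if d1 is not None:
                    extend(cands, [d1], lt_d1m, le, "D1")
            else:
                extend(cands, VM[i - 1][j - 1], lt_mm, le, "M")
                extend(cands, VX[i - 1][j - 1], lt_xm, le, "X")
                extend(cands, VY[i - 1][j - 1], lt_ym, le, "Y")
            VM[i][j] = [_Entry(s, "M", i, j, e) for s, _, e in _top_w(cands, w)]

            # X consumes rna i only; internal, so a match must still follow
            if j <= m - 1:
                cands = []
                extend(cands, VM[i - 1][j], lt_mx, log_q, "M")
                extend(cands, VX[i - 1][j], lt_xx, log_q, "X")
                VX[i][j] = [_Entry(s, "X", i, j, e) for s, _, e in _top_w(cands, w)]

            # Y consumes pair j only; needs a prior and a following match
            if 2 <= j <= m - 1:
                cands = []
                extend(cands, VM[i][j - 1], lt_my, log_o, "M")
                extend(cands, VY[i][j - 1], lt_yy, log_o, "Y")
                VY[i][j] = [_Entry(s, "Y", i, j, e) for s, _, e in _top_w(cands, w)]

    # 3' flank chain at column m
    VD2: list[list[_Entry]] = [[] for _ in range(n + 1)]
    for i in range(1, n + 1):
        cands = []
        extend(cands, VM[i - 1][m], lt_md2, log_q, "M")
        extend(cands, VD2[i - 1], lt_d2d2, log_q, "D2")
        VD2[i] = [_Entry(s, "D2", i, m, e) for s, _, e in _top_w(cands, w)]

    final = []
    extend(final, VM[n][m], lt_mend, 0.0, "M")
    extend(final, VD2[n], lt_d2end, 0.0, "D2")
    final = _top_w(final, w)

    results = []
    seen = set()
    for rank, (score, _, entry) in enumerate(final, start=1):
        res = _traceback(entry, score, rt, emit, base, rna.id, rank)
        if res.path_string in seen:  # defensive; chains are distinct by construction
            continue
        seen.add(res.path_string)
        results.append(res)
    return results


def _traceback(
    entry: _Entry,
    raw_score: float,
    rt: RealizedTransitions,
    emit: np.ndarray,
    base: np.ndarray,
    transcript_id: str,
    rank: int,
) -> AlignmentResult:
    chain = []
    e = entry
    while e is not None and e.state != "start":
        chain.append(e)
        e = e.prev
    chain.reverse()

    steps = []
    for e in chain:
        if e.state == "M":
            steps.append(AlignedStep(state="M", rna_pos=e.i, pair_index=e.j))
        elif e.state == "Y":
            steps.append(AlignedStep(state="Y", rna_pos=None, pair_index=e.j))
        else:  # D1, D2, X consume an RNA base
            steps.append(AlignedStep(state=e.state, rna_pos=e.i, pair_index=None))
    path = ["start"] + [s.state for s in steps] + ["end"]

    m_positions = [s.rna_pos for s in steps if s.state == "M"]
    span = (m_positions[0], m_positions[-1]) if m_positions else (0, 0)

    norm = _normalize(steps, rt, emit, base)
    return AlignmentResult(
        transcript_id=transcript_id,
        path=path,
        steps=steps,
        raw_log_score=raw_score,
        normalized_score=norm,
        span=span,
        rank=rank,
    )


def _normalize(steps, rt: RealizedTransitions, emit, base) -> float:
    log_q = math.log(0.25)
    total = 0.0
    count = 0
    prev = "start"
    flank_entry_seen = False
    for s in steps:
        if s.state == "M":
            le = float(emit[s.pair_index - 1, base[s.rna_pos - 1]])
            if prev in ("start", "D1") and not flank_entry_seen:
                # The entry transition equals T(D1, M) and cancels exactly
                # with the subtracted term, so it is omitted outright; this
                # keeps the score bit-identical across transcript lengths.
                flank_entry_seen = True
                total += le
            else:
                total += rt.log_prob(prev, "M") + le
            count += 1
        elif s.state == "X":
            total += rt.log_prob(prev, "X") + log_q
            count += 1
        prev = s.state
    if count == 0:
        raise ValueError("alignment has no match step; normalized score undefined")
    if not flank_entry_seen:
        total -= rt.log_prob("D1", "M")
    return total / count


def normalize_score(
    result: AlignmentResult,
    params: PairHMMParameters,
    realized: RealizedTransitions,
    pairs: PairSequence,
    rna: RNATranscript,
) -> float:
    """Recompute the normalized score of a decoded alignment.

    Sums the transition + emission log terms of every step entering M or X,
    subtracts log T(D1, M), and divides by the number of M and X steps.
    """
    emit = _emission_matrix(params, pairs)
    base = np.fromiter((_NT_INDEX[b] for b in rna.bases), dtype=np.int64, count=rna.n)
    return _normalize(result.steps, realized, emit, base)


def scan_contiguous(
    params: PairHMMParameters, pairs: PairSequence, rna: RNATranscript
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized scores of every gapless placement of the pair sequence.

    Placement at offset o (1-based start) contacts bases o .. o+m-1 with all
    m pairs in order.  Its normalized score reduces to
    ((m-1) log T(M,M) + sum of match-emission logs) / m, which depends only
    on the contacted window — the basis of the background null model.

    Returns (starts, scores): 1-based start coordinates and the n - m + 1
    normalized scores.
    """
    n, m = rna.n, pairs.m
    if n < m:
        raise ValueError(f"RNA length n={n} must be >= pair count m={m}")
    rt = realize_transitions(params, n, m)
    emit = _emission_matrix(params, pairs)
    base = np.fromiter((_NT_INDEX[b] for b in rna.bases), dtype=np.int64, count=n)

    n_off = n - m + 1
    scores = np.zeros(n_off)
    for t in range(m):
        scores += emit[t, base[t : t + n_off]]
    lt_mm = rt.log_prob("M", "M") if m > 1 else 0.0
    scores = (scores + (m - 1) * lt_mm) / m
    starts = np.arange(1, n_off + 1)
    return starts, scores
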