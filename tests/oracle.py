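"""Independent brute-force oracle: exhaustive enumeration of all legal state
paths of the seven-state alignment model, with scores accumulated step by
step exactly as the dynamic program accumulates them.  Kept free of any code
from the decoder it checks (only the realized-transition lookup and the
legal-transition structure are shared constants of the model definition).
"""

from __future__ import annotations

import math

import numpy as np

LEGAL = {
    "start": ("M", "D1"),
    "D1": ("D1", "M"),
    "M": ("M", "X", "Y", "D2", "end"),
    "X": ("X", "M"),
    "Y": ("Y", "M"),
    "D2": ("D2", "end"),
}

LOG_Q = math.log(0.25)
LOG_O = math.log(1.0 / 400.0)


def enumerate_paths(rt, emit, base, n, m):
    """All complete legal paths as (score, path-tuple), sorted by score desc.

    ``rt`` is a RealizedTransitions, ``emit`` the m x 4 log emission matrix,
    ``base`` the RNA as integer codes.
    """
    results = []

    def rec(state, i, j, score, path):
        if i == n and j == m and state in ("M", "D2"):
            lt = rt.log_prob(state, "end")
            if lt != -math.inf:
                results.append((score + lt, tuple(path)))
        for nxt in LEGAL.get(state, ()):
            if nxt == "end":
                continue
            lt = rt.log_prob(state, nxt)
            if lt == -math.inf:
                continue
            di = 1 if nxt in ("M", "X", "D1", "D2") else 0
            dj = 1 if nxt in ("M", "Y") else 0
            ni, nj = i + di, j + dj
            if ni > n or nj > m:
                continue
            if nxt == "M":
                le = float(emit[nj - 1, base[ni - 1]])
            elif nxt == "Y":
                le = LOG_O
            else:
                le = LOG_Q
            s = score + lt
            s = s + le
            rec(nxt, ni, nj, s, path + [nxt])

    rec("start", 0, 0, 0.0, [])
    results.sort(key=lambda t: -t[0])
    return results


def random_parameters(rng: np.random.Generator, m: int):
    """A random fully-connected parameterization (all transitions positive)
    plus a random pair sequence of length m."""
    from pprbind.hmm import EmissionModel, PairHMMParameters, TransitionModel
    from pprbind.motifs import AA_ALPHABET, MOTIF_TYPES, PairSequence, PairTriple

    rows = {
        "M": dict(zip(("M", "X", "Y", "D2", "end"), rng.dirichlet(np.ones(5)))),
        "X": dict(zip(("X", "M"), rng.dirichlet(np.ones(2)))),
        "Y": dict(zip(("Y", "M"), rng.dirichlet(np.ones(2)))),
    }
    A = rng.random((400, 4, 3))
    A /= A.sum()
    params = PairHMMParameters(
        transitions=TransitionModel(F={}, gamma=0.0, trained_rows=rows),
        emissions=EmissionModel(G=np.zeros_like(A), eta=0.0, A=A),
        metadata={},
    )
    triples = [
        PairTriple(
            aa6=AA_ALPHABET[rng.integers(20)],
            aa1p=AA_ALPHABET[rng.integers(20)],
            motif_type=MOTIF_TYPES[rng.integers(3)],
        )
        for _ in range(m)
    ]
    return params, PairSequence(triples=triples)
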