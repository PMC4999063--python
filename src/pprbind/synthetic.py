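"""Synthetic PPR pair sequences, cognate sites, transcripts and corpora.

The generators realize the empirical PPR recognition code: six (aa6, aa1')
combinations with known nucleotide preference in P- and S-type repeats, plus
two L-type rules (proline at position 6 prefers uracil; asparagine at 1'
paired with I/L/P/T/M at 6 prefers adenine).  Preferences are deterministic
in generation — noise enters only through the fraction of uncoded pairs —
which keeps parameter-recovery tests sharp.

All generators are pure functions of their ``numpy`` Generator, so a seed
fully determines every output.
"""

from __future__ import annotations

import math

import numpy as np

from .hmm import AlignmentStep, TrainingCorpus, TrainingEvent
from .motifs import AA_ALPHABET, NT_ALPHABET, PairSequence, PairTriple, RNATranscript

#: The P/S-scope recognition code: (aa6, aa1') -> preferred nucleotide.
PS_CODE: dict[tuple[str, str], str] = {
    ("T", "D"): "G",
    ("S", "N"): "A",
    ("T", "N"): "A",
    ("N", "D"): "U",
    ("N", "N"): "C",
    ("N", "S"): "C",
}

#: Position-6 residues that, with N at 1', mark an adenine-preferring L repeat.
L_N1P_PARTNERS = frozenset("ILPTM")

#: Concrete coded (aa6, aa1') pairs usable when generating L-type triples.
_L_CODED_PAIRS = [("P", "D"), ("P", "G"), ("I", "N"), ("L", "N"), ("T", "N"), ("M", "N")]


def preferred_nucleotide(aa6: str, aa1p: str, motif_type: str) -> str | None:
    """The coded nucleotide preference of a pair, or None if uncoded.

    P- and S-type repeats follow the six-entry code; L-type repeats follow
    the proline-6 (uracil) and asparagine-1' (adenine) rules only.
    """
    if motif_type == "L":
        if aa6 == "P":
            return "U"
        if aa1p == "N" and aa6 in L_N1P_PARTNERS:
            return "A"
        return None
    return PS_CODE.get((aa6, aa1p))


def _motif_type_cycle(m: int) -> list[str]:
    # PLS-class proteins alternate P, L and S repeats.
    return [("P", "L", "S")[t % 3] for t in range(m)]


def gen_pair_sequence(
    rng: np.random.Generator,
    m: int,
    frac_specific: float = 1.0,
    protein_id: str = "synthetic",
) -> PairSequence:
    """Generate ``m`` triples, ceil(frac_specific * m) of them carrying a
    coded nucleotide preference, over an alternating P/L/S type pattern."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= frac_specific <= 1:
        raise ValueError("frac_specific must lie in [0, 1]")
    types = _motif_type_cycle(m)
    n_specific = math.ceil(frac_specific * m)
    specific_at = set(rng.choice(m, size=n_specific, replace=False).tolist())
    ps_pairs = sorted(PS_CODE)
    triples = []
    for t, mtype in enumerate(types):
        if t in specific_at:
            if mtype == "L":
                aa6, aa1p = _L_CODED_PAIRS[rng.integers(len(_L_CODED_PAIRS))]
            else:
                aa6, aa1p = ps_pairs[rng.integers(len(ps_pairs))]
        else:
            while True:
                aa6 = AA_ALPHABET[rng.integers(len(AA_ALPHABET))]
                aa1p = AA_ALPHABET[rng.integers(len(AA_ALPHABET))]
                if preferred_nucleotide(aa6, aa1p, mtype) is None:
                    break
        triples.append(PairTriple(aa6=aa6, aa1p=aa1p, motif_type=mtype))
    return PairSequence(triples=triples, protein_id=protein_id)


def gen_cognate_site(pairs: PairSequence, rng: np.random.Generator) -> str:
    """The RNA site a pair sequence codes for: preferred base where coded,
    uniform random base otherwise."""
    site = []
    for tr in pairs:
        pref = preferred_nucleotide(tr.aa6, tr.aa1p, tr.motif_type)
        site.append(pref if pref is not None else NT_ALPHABET[rng.integers(4)])
    return "".join(site)


def gen_transcript(
    rng: np.random.Generator,
    length: int,
    transcript_id: str = "synthetic",
    composition: tuple[float, float, float, float] | None = None,
) -> RNATranscript:
    """A random transcript; ``composition`` gives A/C/G/U weights (uniform by
    default — organellar transcripts are AU-rich, so this is a knob)."""
    p = None if composition is None else np.asarray(composition) / sum(composition)
    bases = "".join(rng.choice(list(NT_ALPHABET), size=length, p=p))
    return RNATranscript(id=transcript_id, bases=bases)


def plant_site(
    site: str,
    transcript_length: int,
    rng: np.random.Generator,
    transcript_id: str = "planted",
    composition: tuple[float, float, float, float] | None = None,
) -> tuple[RNATranscript, int]:
    """Embed a site in a random transcript at a uniform random offset.

    Returns the transcript and the 1-based offset of the site's first base.
    """
    m = len(site)
    if transcript_length < m:
        raise ValueError(
            f"transcript length {transcript_length} < site length {m}"
        )
    background = gen_transcript(rng, transcript_length, transcript_id, composition)
    offset0 = int(rng.integers(0, transcript_length - m + 1))
    bases = background.bases[:offset0] + site + background.bases[offset0 + m :]
    return RNATranscript(id=transcript_id, bases=bases), offset0 + 1


def gen_training_corpus(
    rng: np.random.Generator,
    n_events: int,
    m_range: tuple[int, int] = (8, 16),
    frac_specific: float = 0.8,
    flank_range: tuple[int, int] = (0, 30),
) -> TrainingCorpus:
    """A corpus of gapless binding events: each event aligns a generated pair
    sequence contiguously to its cognate site, flanked by unaligned RNA.

    Event structure mirrors experimentally curated binding diagrams: a 5'
    flank of D1 steps, m match steps, a 3' flank of D2 steps; no internal
    gaps (PLS proteins bind contiguously).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    events = []
    for k in range(n_events):
        m = int(rng.integers(m_range[0], m_range[1] + 1))
        pairs = gen_pair_sequence(rng, m, frac_specific, protein_id=f"ev{k:04d}")
        site = gen_cognate_site(pairs, rng)
        f5 = int(rng.integers(flank_range[0], flank_range[1] + 1))
        f3 = int(rng.integers(flank_range[0], flank_range[1] + 1))
        steps = [
            AlignmentStep(state="D1", nucleotide=NT_ALPHABET[rng.integers(4)])
            for _ in range(f5)
        ]
        steps += [
            AlignmentStep(
                state="M",
                aa6=tr.aa6,
                aa1p=tr.aa1p,
                motif_type=tr.motif_type,
                nucleotide=b,
            )
            for tr, b in zip(pairs, site)
        ]
        steps += [
            AlignmentStep(state="D2", nucleotide=NT_ALPHABET[rng.integers(4)])
            for _ in range(f3)
        ]
        events.append(TrainingEvent(event_id=f"ev{k:04d}", steps=steps))
    return TrainingCorpus(events=events)
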