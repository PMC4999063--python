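"""Motif annotation and pair-sequence construction for PLS-class PPR proteins.

PPR (pentatricopeptide repeat) proteins are built from tandem ~35-residue
helical repeats.  Repeats are typed by length: exactly 35 residues is a
P motif, shorter than 35 an S motif, longer an L motif.  The nucleotide
contacted by a repeat is specified jointly by the residue at position 6 of
that repeat and the residue at position 1 of the *next* repeat (position 1').
A protein with ``l`` annotated motifs therefore yields ``l - 1`` ordered
(aa6, aa1', motif_type) triples — the pair sequence that is aligned to RNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGU"
MOTIF_TYPES = "PLS"

# Degenerate consensus of a canonical 35-residue P-type PPR repeat, used by
# the fallback scanner when no motif table is supplied.  Matching is by
# fractional identity against this consensus; random sequence scores ~0.05.
PPR_CONSENSUS = "VTYNTLISGLCKAGRLDEAMELFREMKEKGIVPDV"
SCANNER_MIN_IDENTITY = 0.4


class MotifError(ValueError):
    """Invalid motif annotation (length, overlap, or out-of-range)."""


@dataclass(frozen=True)
class MotifAnnotation:
    """One PPR repeat: 1-based inclusive residue span plus derived type."""

    start: int
    end: int
    motif_type: str = field(default="", compare=False)

    def __post_init__(self):
        if self.start < 1:
            raise MotifError(f"motif start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise MotifError(f"motif end {self.end} < start {self.start}")
        if self.length < 6:
            raise MotifError(
                f"motif [{self.start},{self.end}] has length {self.length} < 6; "
                "position 6 is undefined"
            )
        expected = classify_motif_type(self.length)
        if self.motif_type and self.motif_type != expected:
            raise MotifError(
                f"motif of length {self.length} must be type {expected}, "
                f"got {self.motif_type!r}"
            )
        if not self.motif_type:
            object.__setattr__(self, "motif_type", expected)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PPRProtein:
    """Amino-acid sequence with its ordered, non-overlapping motif list."""

    id: str
    residues: str
    motifs: list[MotifAnnotation]

    def __post_init__(self):
        validate_motif_list(self.motifs, len(self.residues))

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)


@dataclass(frozen=True)
class PairTriple:
    """One (position-6 residue, position-1' residue, motif type) triple.

    The motif type is that of the repeat contributing position 6 — the repeat
    whose helix contacts the nucleotide.
    """

    aa6: str
    aa1p: str
    motif_type: str


@dataclass
class PairSequence:
    """The ordered (6, 1') pair sequence of a PPR protein; length l - 1."""

    triples: list[PairTriple]
    protein_id: str = ""

    @property
    def m(self) -> int:
        return len(self.triples)

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)

    def __getitem__(self, i):
        return self.triples[i]


@dataclass
class RNATranscript:
    """A sense-strand RNA sequence over {A, C, G, U} (T normalized to U)."""

    id: str
    bases: str

    def __post_init__(self):
        self.bases = self.bases.upper().replace("T", "U")
        bad = set(self.bases) - set(NT_ALPHABET)
        if bad:
            raise ValueError(
                f"transcript {self.id!r} contains non-RNA symbols: {sorted(bad)}"
            )

    @property
    def n(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


def classify_motif_type(length_aa: int) -> str:
    """Type a PPR repeat by its residue count: <35 -> S, ==35 -> P, >35 -> L."""
    if length_aa < 6:
        raise MotifError(f"motif length {length_aa} < 6: position 6 undefined")
    if length_aa < 35:
        return "S"
    if length_aa == 35:
        return "P"
    return "L"


def validate_motif_list(motifs: list[MotifAnnotation], seq_len: int) -> None:
    """Check sortedness, non-overlap and in-range spans; raise listing offenders."""
    bad: list[str] = []
    for k, m in enumerate(motifs):
        if m.end > seq_len:
            bad.append(f"motif {k + 1} [{m.start},{m.end}] exceeds sequence length {seq_len}")
        if k > 0:
            prev = motifs[k - 1]
            if m.start <= prev.end:
                bad.append(
                    f"motif {k + 1} [{m.start},{m.end}] overlaps or precedes "
                    f"motif {k} [{prev.start},{prev.end}]"
                )
    if bad:
        raise MotifError("; ".join(bad))


def annotate_motifs(
    residues: str,
    provided: list[tuple[int, int]] | None = None,
    mode: str = "provided",
) -> list[MotifAnnotation]:
    """Build the typed motif list for a protein sequence.

    ``provided`` mode consumes a user-supplied list of 1-based inclusive
    (start, end) spans, as produced by any external repeat annotator; types are
    always derived from span lengths, never read from the table.  ``scanner``
    mode runs the built-in consensus scanner (fixed 35-residue windows scored
    by identity against :data:`PPR_CONSENSUS`), a fallback that only detects
    canonical-length repeats.
    """
    if mode == "provided":
        if provided is None:
            raise MotifError("provided mode requires a motif table")
        motifs = sorted(
            (MotifAnnotation(start=s, end=e) for s, e in provided),
            key=lambda m: m.start,
        )
        validate_motif_list(motifs, len(residues))
        return motifs
    if mode == "scanner":
        return scan_ppr_motifs(residues)
    raise ValueError(f"unknown annotation mode {mode!r}")


def scan_ppr_motifs(
    residues: str,
    min_identity: float = SCANNER_MIN_IDENTITY,
) -> list[MotifAnnotation]:
    """Greedy left-to-right scan for canonical 35-residue PPR repeats.

    Each window is scored as fractional identity to the degenerate consensus;
    windows at or above ``min_identity`` are accepted and the scan resumes
    after the accepted repeat (repeats never overlap).  Random sequence has
    expected identity ~1/20, so the default threshold makes spurious hits
    vanishingly rare while still tolerating substantial repeat divergence.
    """
    residues = residues.upper()
    w = len(PPR_CONSENSUS)
    hits: list[MotifAnnotation] = []
    pos = 0
    while pos + w <= len(residues):
        window = residues[pos : pos + w]
        ident = sum(a == b for a, b in zip(window, PPR_CONSENSUS)) / w
        if ident >= min_identity:
            hits.append(MotifAnnotation(start=pos + 1, end=pos + w))
            pos += w
        else:
            pos += 1
    return hits


def extract_pair_sequence(protein: PPRProtein) -> PairSequence:
    """Extract the ordered (aa6, aa1', type) triples from adjacent motifs.

    Triple ``t`` pairs residue 6 of motif ``t`` with residue 1 of motif
    ``t + 1`` and carries the type of motif ``t`` (the position-6 motif).
    """
    if protein.n_motifs < 2:
        raise MotifError(
            f"protein {protein.id!r} has {protein.n_motifs} motif(s); "
            "at least 2 are required to form a pair sequence"
        )
    triples = []
    for a, b in zip(protein.motifs, protein.motifs[1:]):
        aa6 = protein.residues[a.start - 1 + 5]  # position 6, 1-based
        aa1p = protein.residues[b.start - 1]  # position 1 of next motif
        triples.append(PairTriple(aa6=aa6, aa1p=aa1p, motif_type=a.motif_type))
    return PairSequence(triples=triples, protein_id=protein.id)


@dataclass
class EditSiteWindow:
    """An upstream window ending at an edit site, with its coordinate map."""

    transcript_id: str
    bases: str
    start: int  # 1-based transcript coordinate of window base 1
    end: int  # 1-based transcript coordinate of the last window base (= edit_pos)
    edit_pos: int

    def to_transcript(self, local_pos: int) -> int:
        """Map a 1-based window-local coordinate to a transcript coordinate."""
        if not 1 <= local_pos <= len(self.bases):
            raise IndexError(f"window-local position {local_pos} outside [1,{len(self.bases)}]")
        return self.start + local_pos - 1

    def to_local(self, transcript_pos: int) -> int:
        """Map a 1-based transcript coordinate into the window."""
        if not self.start <= transcript_pos <= self.end:
            raise IndexError(
                f"transcript position {transcript_pos} outside window [{self.start},{self.end}]"
            )
        return transcript_pos - self.start + 1

    def is_anchored(self, last_match_pos: int) -> bool:
        """True if an alignment's final matched base sits 4 bases upstream of the edit site.

        PLS editing factors bind so that the terminal S motif contacts the
        nucleotide four positions upstream of the edited cytidine.
        """
        return last_match_pos == self.edit_pos - 4


def edit_site_window(
    transcript: RNATranscript, edit_pos: int, window_len: int
) -> EditSiteWindow:
    """Extract the ``window_len`` bases ending at ``edit_pos`` (inclusive).

    The window is clipped at the transcript start (with a warning) when the
    edit site is closer than ``window_len`` to the 5' end.
    """
    if not 1 <= edit_pos <= transcript.n:
        raise IndexError(
            f"edit position {edit_pos} outside transcript {transcript.id!r} [1,{transcript.n}]"
        )
    if window_len < 1:
        raise ValueError("window_len must be positive")
    start = edit_pos - window_len + 1
    if start < 1:
        warnings.warn(
            f"window of length {window_len} upstream of position {edit_pos} "
            f"clipped at transcript start ({transcript.id!r})",
            stacklevel=2,
        )
        start = 1
    return EditSiteWindow(
        transcript_id=transcript.id,
        bases=transcript.bases[start - 1 : edit_pos],
        start=start,
        end=edit_pos,
        edit_pos=edit_pos,
    )
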