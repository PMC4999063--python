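"""File I/O: FASTA, motif tables, training corpora, hits and backgrounds.

All tabular formats are plain TSV with a commented header block (lines
starting with '#') recording the tool version and the resolved run
configuration, so every output is self-describing and reproducible.
"""

from __future__ import annotations

import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .hmm import GAP, AlignmentStep, TrainingCorpus, TrainingEvent
from .motifs import AA_ALPHABET, NT_ALPHABET, RNATranscript

CORPUS_COLUMNS = ("event_id", "step", "state", "aa6", "aa1p", "motif_type", "nucleotide")
HITS_COLUMNS = (
    "transcript_id",
    "start",
    "end",
    "rank",
    "raw_log_score",
    "normalized_score",
    "pvalue",
    "padj",
    "path",
    "pairs_string",
    "site_string",
)


class ParseError(ValueError):
    pass


def read_fasta(path: str | Path, alphabet: str = "rna"):
    """Read FASTA records; RNA mode upper-cases and maps T to U.

    Returns (records, excluded): for RNA, records are RNATranscript; for
    protein, (id, sequence) tuples.  Records containing out-of-alphabet
    symbols are excluded with a warning and listed in ``excluded``.
    """
    path = Path(path)
    records, excluded = [], []
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    for rec in parsed:
        seq = str(rec.seq).upper()
        if alphabet == "rna":
            seq = seq.replace("T", "U")
            bad = set(seq) - set(NT_ALPHABET)
        elif alphabet == "protein":
            bad = set(seq) - set(AA_ALPHABET) - set("XBZ*")
        else:
            raise ValueError(f"unknown alphabet {alphabet!r}")
        if bad:
            warnings.warn(
                f"{path}: record {rec.id!r} contains disallowed symbols "
                f"{sorted(bad)}; excluded",
                stacklevel=2,
            )
            excluded.append(rec.id)
            continue
        if alphabet == "rna":
            records.append(RNATranscript(id=rec.id, bases=seq))
        else:
            records.append((rec.id, seq))
    return records, excluded


def write_fasta(path: str | Path, records) -> None:
    """Write (id, sequence) pairs or RNATranscript objects as FASTA."""
    out = []
    for r in records:
        if isinstance(r, RNATranscript):
            out.append(SeqRecord(Seq(r.bases), id=r.id, description=""))
        else:
            rid, seq = r
            out.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")


def write_windows(path: str | Path, windows) -> None:
    """Write edit-site windows as FASTA, transcript coordinates in the
    description: `>id window=START-END edit_pos=P`."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f">{w.transcript_id} window={w.start}-{w.end} edit_pos={w.edit_pos}\n"
            )
            fh.write(w.bases + "\n")


def read_motif_table(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a motif table: TSV with header `protein_id  start  end`
    (1-based inclusive; the motif type is derived from length, never read)."""
    path = Path(path)
    table: dict[str, list[tuple[int, int]]] = {}
    header_seen = False
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if not header_seen:
            if fields[:3] != ["protein_id", "start", "end"]:
                raise ParseError(
                    f"{path}:{ln}: expected header 'protein_id\\tstart\\tend'"
                )
            header_seen = True
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}:{ln}: expected 3 fields, got {len(fields)}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: non-integer coordinate") from exc
        table.setdefault(fields[0], []).append((start, end))
    return table


def _header(config: dict | None) -> str:
    lines = [f"# pprbind {__version__}"]
    for k, v in (config or {}).items():
        lines.append(f"# {k} = {v}")
    return "\n".join(lines) + "\n"


def write_corpus(path: str | Path, corpus: TrainingCorpus, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("\t".join(CORPUS_COLUMNS) + "\n")
        for ev in corpus.events:
            for i, s in enumerate(ev.steps, start=1):
                fh.write(
                    "\t".join(
                        [ev.event_id, str(i), s.state, s.aa6, s.aa1p, s.motif_type, s.nucleotide]
                    )
                    + "\n"
                )


def read_corpus(path: str | Path) -> TrainingCorpus:
    """Read the one-row-per-alignment-step corpus dialect and validate it.

    Columns: event_id, step, state, aa6, aa1p, motif_type, nucleotide; '-'
    marks non-emitted fields.  Steps must be numbered 1..k within an event.
    """
    path = Path(path)
    events: dict[str, list[tuple[int, AlignmentStep]]] = {}
    order: list[str] = []
    header_seen = False
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if not header_seen:
            if tuple(fields[: len(CORPUS_COLUMNS)]) != CORPUS_COLUMNS:
                raise ParseError(f"{path}:{ln}: bad corpus header")
            header_seen = True
            continue
        if len(fields) < len(CORPUS_COLUMNS):
            raise ParseError(f"{path}:{ln}: expected {len(CORPUS_COLUMNS)} fields")
        ev_id, step_s, state, aa6, aa1p, mtype, nt = fields[: len(CORPUS_COLUMNS)]
        try:
            step_no = int(step_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: non-integer step for event {ev_id!r}") from exc
        if ev_id not in events:
            events[ev_id] = []
            order.append(ev_id)
        events[ev_id].append(
            (step_no, AlignmentStep(state=state, aa6=aa6, aa1p=aa1p, motif_type=mtype, nucleotide=nt))
        )
    out = []
    for ev_id in order:
        numbered = events[ev_id]
        if [k for k, _ in numbered] != list(range(1, len(numbered) + 1)):
            raise ParseError(
                f"{path}: event {ev_id!r}: steps must be numbered 1..{len(numbered)} in order"
            )
        out.append(TrainingEvent(event_id=ev_id, steps=[s for _, s in numbered]))
    return TrainingCorpus(events=out)  # validates state walks and fields


def write_pairs(path: str | Path, pairs_by_protein: dict, config: dict | None = None) -> None:
    """Write pair sequences: TSV `protein_id  index  aa6  aa1p  motif_type`."""
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("protein_id\tindex\taa6\taa1p\tmotif_type\n")
        for pid, pairs in pairs_by_protein.items():
            for t, tr in enumerate(pairs, start=1):
                fh.write(f"{pid}\t{t}\t{tr.aa6}\t{tr.aa1p}\t{tr.motif_type}\n")


def read_pairs(path: str | Path) -> dict:
    """Read pair sequences written by :func:`write_pairs`."""
    from .motifs import PairSequence, PairTriple

    path = Path(path)
    out: dict[str, list] = {}
    header_seen = False
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if not header_seen:
            if fields[:5] != ["protein_id", "index", "aa6", "aa1p", "motif_type"]:
                raise ParseError(f"{path}:{ln}: bad pairs header")
            header_seen = True
            continue
        pid, _, aa6, aa1p, mtype = fields[:5]
        out.setdefault(pid, []).append(PairTriple(aa6=aa6, aa1p=aa1p, motif_type=mtype))
    return {
        pid: PairSequence(triples=triples, protein_id=pid)
        for pid, triples in out.items()
    }


def write_hits(path: str | Path, rows: list[dict], config: dict | None = None) -> None:
    """Write alignment hits; rows lacking pvalue/padj get '-' (no-database mode)."""
    with open(path, "w") as fh:
        fh.write(_header(config))
        cols = list(HITS_COLUMNS)
        if rows and "pvalue" not in rows[0]:
            cols = [c for c in cols if c not in ("pvalue", "padj")]
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, GAP)) for c in cols) + "\n")


def write_background(path: str | Path, background, config: dict | None = None) -> None:
    """Background cache: one row per contiguous placement, with the fitted
    normal parameters in the header."""
    cfg = dict(config or {})
    cfg.update(
        mu=repr(background.mu), sigma=repr(background.sigma), count=background.count
    )
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        fh.write("transcript_id\tstart\tnormalized_score\n")
        if background.placements is not None:
            for tr_id, starts, scores in background.placements:
                for st, sc in zip(starts, scores):
                    fh.write(f"{tr_id}\t{st}\t{sc!r}\n")
        else:
            for sc in background.scores:
                fh.write(f"-\t-\t{sc!r}\n")
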