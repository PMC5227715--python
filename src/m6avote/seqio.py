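"""FASTA input, candidate-window extraction and tab-delimited site reports.

Coordinates are 1-based, fully closed, on the given (sense) strand. Candidate
windows are odd-length stretches centered on an adenosine; the default window
length is 51 nt, so the central residue sits at window offset 26 (1-based).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .exceptions import AlphabetError, FastaFormatError

RNA_ALPHABET = frozenset("ACGU")
_INPUT_ALPHABET = frozenset("ACGUTacgut")

#: Class labels used in reports.
POSITIVE_LABEL = "m6A"
NEGATIVE_LABEL = "non-m6A"

DEFAULT_WINDOW_LEN = 51

REPORT_COLUMNS = (
    "transcript_id",
    "center_pos",
    "label",
    "V_positive",
    "V_negative",
    "psednc_label",
    "motif_label",
    "gkm_label",
)


def normalize_residues(raw: str, seq_id: str = "<anonymous>") -> str:
    """Uppercase and map DNA T to RNA U; reject anything outside {A,C,G,U,T}."""
    for i, ch in enumerate(raw):
        if ch not in _INPUT_ALPHABET:
            raise AlphabetError(seq_id, i + 1, ch)
    return raw.upper().replace("T", "U")


@dataclass(frozen=True)
class RnaSequence:
    """A normalized RNA sequence (residues over {A,C,G,U})."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise FastaFormatError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            offset = next(
                i + 1 for i, c in enumerate(self.residues) if c not in RNA_ALPHABET
            )
            raise AlphabetError(self.id, offset, self.residues[offset - 1])

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SiteWindow:
    """An odd-length candidate window centered on an adenosine.

    ``center_pos`` is the 1-based position of the central A on the source
    transcript. ``label`` is :data:`POSITIVE_LABEL`, :data:`NEGATIVE_LABEL`
    or ``None`` for unlabeled queries.
    """

    transcript_id: str
    center_pos: int
    residues: str
    label: Optional[str] = field(default=None)

    def __post_init__(self):
        n = len(self.residues)
        if n % 2 != 1:
            raise ValueError(f"window length must be odd, got {n}")
        mid = n // 2
        if self.residues[mid] != "A":
            raise ValueError(
                f"window on {self.transcript_id!r} centered at {self.center_pos} "
                f"has {self.residues[mid]!r} at its center, expected 'A'"
            )
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValueError(f"window contains non-RNA residues: {sorted(bad)}")
        if self.label not in (None, POSITIVE_LABEL, NEGATIVE_LABEL):
            raise ValueError(f"unknown label {self.label!r}")


def read_fasta(path) -> list[RnaSequence]:
    """Read a FASTA file into an ordered list of :class:`RnaSequence`.

    Lowercase is folded to uppercase and T is mapped to U. The record id is
    the header token up to the first whitespace. Multi-line records and blank
    lines are fine; degenerate IUPAC codes are rejected.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    stripped = text.lstrip()
    if not stripped:
        raise FastaFormatError(f"{path}: empty FASTA file")
    if not stripped.startswith(">"):
        raise FastaFormatError(f"{path}: record 1 has no '>' header")
    records = []
    for idx, (header, seq) in enumerate(SimpleFastaParser(io.StringIO(text)), 1):
        seq_id = header.split()[0] if header.split() else ""
        if not seq_id:
            raise FastaFormatError(f"{path}: record {idx} has an empty header")
        if not seq:
            raise FastaFormatError(
                f"{path}: record {idx} ({seq_id!r}) has no residues"
            )
        records.append(RnaSequence(id=seq_id, residues=normalize_residues(seq, seq_id)))
    return records


def write_fasta(records: Iterable[RnaSequence], path, width: int = 70) -> None:
    """Write records back out; inverse of :func:`read_fasta` on (id, residues)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def extract_windows(
    seq: RnaSequence, window_len: int = DEFAULT_WINDOW_LEN
) -> list[SiteWindow]:
    """All unlabeled candidate windows of ``seq``: one per adenosine that has
    at least ``(window_len - 1) // 2`` residues on each side, ordered by
    center position. A transcript too short or with no eligible A yields an
    empty list."""
    if window_len % 2 != 1 or window_len < 1:
        raise ValueError(f"window_len must be odd and positive, got {window_len}")
    flank = (window_len - 1) // 2
    out = []
    res = seq.residues
    for i in range(flank, len(res) - flank):
        if res[i] == "A":
            out.append(
                SiteWindow(
                    transcript_id=seq.id,
                    center_pos=i + 1,
                    residues=res[i - flank : i + flank + 1],
                )
            )
    return out


def write_site_report(predictions: Sequence, path) -> None:
    """Write a tab-delimited site report.

    ``predictions`` holds objects with attributes ``window``, ``label``,
    ``v_positive``, ``v_negative`` and ``base_labels`` (psednc, motif, gkm) —
    see :class:`m6avote.model.PredictionRecord`.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for rec in predictions:
            w = rec.window
            row = (
                w.transcript_id,
                str(w.center_pos),
                rec.label,
                f"{rec.v_positive:.6f}",
                f"{rec.v_negative:.6f}",
                *rec.base_labels,
            )
            fh.write("\t".join(row) + "\n")


def read_site_report(path) -> list[dict]:
    """Parse a site report back into a list of dicts (round-trip of the writer)."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != REPORT_COLUMNS:
            raise FastaFormatError(f"{path}: unexpected report header {header}")
        rows = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            row = dict(zip(REPORT_COLUMNS, fields))
            row["center_pos"] = int(row["center_pos"])
            row["V_positive"] = float(row["V_positive"])
            row["V_negative"] = float(row["V_negative"])
            rows.append(row)
        return rows
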