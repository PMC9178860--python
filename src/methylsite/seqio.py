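"""FASTA I/O and fixed-length window extraction around candidate sites.

Sequences live on the five-symbol alphabet ``{A, C, G, T, -}``: the four
nucleotides (RNA ``U`` is normalized to ``T`` on input) plus the gap pad
``-`` used to fill window positions that fall outside the source sequence.
Coordinates are 1-based and intervals fully closed, so a window of
half-width ``n`` centered at position ``p`` covers ``[p - n, p + n]`` and
always has length ``2n + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: the full window alphabet: four nucleotides plus the gap pad
ALPHABET = "ACGT-"
#: nucleotide sub-alphabet (no gap)
NUCLEOTIDES = "ACGT"
GAP = "-"

NormalizePolicy = Literal["strict", "mask"]


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed or violates the alphabet."""


class SequenceValidationError(ValueError):
    """Raised by strict normalization on a disallowed character."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over ``{A,C,G,T,-}`` after normalization."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r}: disallowed characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceWindow:
    """A ``2n+1``-length window centered on a candidate site.

    ``center_pos`` is the 1-based position of the site in the source
    sequence; positions outside the source are padded with ``-``, which by
    construction can only occur as a contiguous prefix and/or suffix run.
    ``label`` is 0/1 or ``None`` for unlabeled windows.
    """

    source_id: str
    center_pos: int
    half_width: int
    window: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if len(self.window) != 2 * self.half_width + 1:
            raise ValueError(
                f"window length {len(self.window)} != 2n+1 = "
                f"{2 * self.half_width + 1}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")

    @property
    def window_id(self) -> str:
        return f"{self.source_id}:{self.center_pos}"

    @property
    def center_char(self) -> str:
        return self.window[self.half_width]


def normalize_sequence(raw: str, policy: NormalizePolicy = "strict") -> str:
    """Uppercase, map U->T, keep ``-``; police everything else.

    Under ``strict`` any character outside ``{A,C,G,T,U,-}`` (case
    insensitive) raises :class:`SequenceValidationError` naming the 1-based
    position. Under ``mask`` such characters (e.g. IUPAC ambiguity codes)
    become ``-`` with a logged warning, keeping the 5-symbol alphabet.
    """
    if not raw:
        raise ValueError("empty sequence")
    up = raw.upper().replace("U", "T")
    if set(up) <= set(ALPHABET):
        return up
    if policy == "strict":
        for pos, ch in enumerate(up, start=1):
            if ch not in ALPHABET:
                raise SequenceValidationError(
                    f"disallowed character {raw[pos - 1]!r} at position {pos}"
                )
    masked = "".join(ch if ch in ALPHABET else GAP for ch in up)
    n_masked = sum(1 for a, b in zip(up, masked) if a != b)
    logger.warning("masked %d ambiguous character(s) to '-'", n_masked)
    return masked


def read_fasta(
    path: str | Path, policy: NormalizePolicy = "strict"
) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Entry order is preserved. Malformed entries (text before the first
    header, empty sequences) and alphabet violations raise
    :class:`FastaParseError` naming the offending record.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        first = text.splitlines()[0] if text.splitlines() else ""
        raise FastaParseError(
            f"{path}: expected FASTA header '>' on line 1, got {first!r}"
        )
    records: list[SequenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(StringIO(text), "fasta"), start=1):
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"{path}: entry {i} ({rec.id!r}) is empty")
        try:
            records.append(SequenceRecord(rec.id, normalize_sequence(seq, policy)))
        except (ValueError, SequenceValidationError) as exc:
            raise FastaParseError(f"{path}: entry {i} ({rec.id!r}): {exc}") from exc
    if not records and stripped:
        raise FastaParseError(f"{path}: no FASTA entries parsed")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as multi-line-free FASTA (one sequence line each)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def extract_window(
    rec: SequenceRecord, center_pos: int, n: int, label: int | None = None
) -> SequenceWindow:
    """Extract the ``2n+1`` window centered at 1-based ``center_pos``.

    Source positions ``[center_pos - n, center_pos + n]``; positions outside
    ``[1, len(rec)]`` yield the pad character ``-``.
    """
    if not 1 <= center_pos <= len(rec.sequence):
        raise IndexError(
            f"center_pos {center_pos} outside [1, {len(rec.sequence)}] "
            f"for record {rec.id!r}"
        )
    if n < 1:
        raise ValueError("half-width n must be >= 1")
    left = center_pos - n
    right = center_pos + n
    core = rec.sequence[max(left, 1) - 1 : min(right, len(rec.sequence))]
    pad_l = max(0, 1 - left)
    pad_r = max(0, right - len(rec.sequence))
    return SequenceWindow(
        source_id=rec.id,
        center_pos=center_pos,
        half_width=n,
        window=GAP * pad_l + core + GAP * pad_r,
        label=label,
    )


def write_labels(windows: Iterable[SequenceWindow], path: str | Path) -> None:
    """Write the tab-separated label file: ``window_id<TAB>label``."""
    with open(path, "w") as fh:
        for w in windows:
            if w.label is None:
                raise ValueError(f"window {w.window_id} is unlabeled")
            fh.write(f"{w.window_id}\t{w.label}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read the label TSV into ``{window_id: label}``."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise ValueError(f"{path}: malformed label line {lineno}: {line!r}")
        labels[parts[0]] = int(parts[1])
    return labels
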