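"""Sequence containers, FASTA I/O, background chunking and window extraction.

The classifier operates on fixed-length DNA words: experimentally verified
binding sites of a common length ``L`` form the foreground class, and every
overlapping ``L``-mer of a chunked genomic background forms the background
class.  This module provides the alphabet/sequence representation, FASTA
reading and writing (via Biopython), the chunking and window-extraction
steps, and the labeled-data assembly used by training and evaluation.

Conventions
-----------
* Forward strand only; reverse complements are never considered.
* Coordinates are 0-based, half-open.
* Symbols outside the alphabet (``N`` and other IUPAC ambiguity codes) are
  encoded as the sentinel ``-1``; any window or site containing such a
  symbol is dropped with a logged warning, since the probabilistic models
  have no ambiguity handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Sentinel residue code for symbols outside the alphabet.
UNRESOLVED = -1


class FastaFormatError(ValueError):
    """Raised when a file is not parseable as FASTA."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered symbol alphabet; the index of a symbol is its position.

    The canonical DNA alphabet is ``ACGT`` (A=0, C=1, G=2, T=3).  The code
    is generic in the alphabet size ``K``.
    """

    symbols: str = "ACGT"

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least two symbols")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def encode(self, text: str) -> np.ndarray:
        """Map a string to residue indices; unknown symbols become -1.

        Lowercase letters are normalized to uppercase first.
        """
        table = np.full(256, UNRESOLVED, dtype=np.int16)
        for i, s in enumerate(self.symbols):
            table[ord(s)] = i
            table[ord(s.lower())] = i
        raw = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
        return table[raw].astype(np.int16)

    def decode(self, residues: np.ndarray) -> str:
        out = []
        for r in residues:
            out.append(self.symbols[r] if r >= 0 else "N")
        return "".join(out)


DNA = Alphabet("ACGT")


@dataclass
class Sequence:
    """A named sequence stored as a vector of alphabet indices."""

    id: str
    residues: np.ndarray

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=np.int16)

    @classmethod
    def from_text(cls, id: str, text: str, alphabet: Alphabet = DNA) -> "Sequence":
        return cls(id=id, residues=alphabet.encode(text))

    @property
    def length(self) -> int:
        return int(self.residues.size)

    @property
    def is_clean(self) -> bool:
        """True when every residue is a proper alphabet index."""
        return bool(self.residues.size == 0 or self.residues.min() >= 0)

    def to_text(self, alphabet: Alphabet = DNA) -> str:
        return alphabet.decode(self.residues)


@dataclass
class LabeledData:
    """Equal-length sequences with binary class labels (0=bg, 1=fg)."""

    sequences: list
    labels: np.ndarray
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.sequences) != self.labels.size:
            raise ValueError("sequences and labels must have equal length")
        if self.labels.size and not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0 (background) or 1 (foreground)")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def L(self) -> int:
        if not self.sequences:
            raise ValueError("empty data set has no defined length")
        return self.sequences[0].length

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=2)

    def matrix(self) -> np.ndarray:
        """Residues as an (N, L) integer matrix; requires equal lengths."""
        if self._matrix is None:
            if not self.sequences:
                self._matrix = np.zeros((0, 0), dtype=np.int16)
            else:
                lens = {s.length for s in self.sequences}
                if len(lens) != 1:
                    raise ValueError(f"sequences have unequal lengths: {sorted(lens)}")
                self._matrix = np.vstack([s.residues for s in self.sequences])
        return self._matrix

    def subset(self, idx: np.ndarray) -> "LabeledData":
        idx = np.asarray(idx)
        return LabeledData([self.sequences[i] for i in idx], self.labels[idx])

    @classmethod
    def from_classes(cls, bg: Iterable[Sequence], fg: Iterable[Sequence]) -> "LabeledData":
        bg, fg = list(bg), list(fg)
        labels = np.concatenate([np.zeros(len(bg), int), np.ones(len(fg), int)])
        return cls(bg + fg, labels)


def read_fasta(path, alphabet: Alphabet = DNA) -> list:
    """Read a FASTA file into a list of :class:`Sequence`, in file order.

    Record ids are taken up to the first whitespace; lowercase residues are
    uppercased.  Symbols outside the alphabet are kept as the ``-1``
    sentinel so downstream filtering can drop affected windows.  An empty
    file yields an empty list.
    """
    path = Path(path)
    seqs: list = []
    with open(path) as fh:
        # Reject text before the first header: SeqIO silently skips it.
        for line in fh:
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: sequence data before first '>' header"
                )
            break
        fh.seek(0)
        try:
            for rec in SeqIO.parse(fh, "fasta"):
                seqs.append(Sequence(id=rec.id, residues=alphabet.encode(str(rec.seq))))
        except ValueError as exc:  # pragma: no cover - SeqIO internal errors
            raise FastaFormatError(f"{path}: {exc}") from exc
    return seqs


def write_fasta(seqs: Iterable[Sequence], path, alphabet: Alphabet = DNA) -> None:
    """Write sequences as multi-line FASTA, 60 columns per line."""
    records = [
        SeqRecord(Seq(s.to_text(alphabet)), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def chunk_sequences(seqs: TypingSequence[Sequence], max_len: int = 100) -> list:
    """Split each sequence left-to-right into non-overlapping pieces.

    Every piece has length ``max_len`` except possibly the last one.  The
    total residue count is conserved exactly.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    out = []
    for s in seqs:
        for start in range(0, s.length, max_len):
            end = min(start + max_len, s.length)
            out.append(Sequence(id=f"{s.id}:{start}-{end}", residues=s.residues[start:end]))
    return out


def extract_windows(seqs: TypingSequence[Sequence], L: int = 16) -> list:
    """All overlapping forward-strand windows of length ``L``, in order.

    Sequences shorter than ``L`` yield no windows.  Windows containing an
    unresolved symbol are discarded; the number discarded is logged.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    out = []
    dropped = 0
    for s in seqs:
        res = s.residues
        n = res.size
        if n < L:
            continue
        bad = res < 0
        for start in range(n - L + 1):
            if bad[start : start + L].any():
                dropped += 1
                continue
            out.append(Sequence(id=f"{s.id}|{start}", residues=res[start : start + L]))
    if dropped:
        logger.warning("extract_windows: discarded %d windows with ambiguous symbols", dropped)
    return out


@dataclass
class SiteBackgroundData:
    """A binding-site classification data set before windowing.

    Holds the foreground sites (each exactly ``L`` residues) and the
    background *chunks* (pieces of at most ~100 bp).  Keeping the chunks
    un-windowed is deliberate: the hold-out protocol partitions chunks, not
    windows, so that overlapping ``L``-mers from one chunk never straddle
    the train/test boundary.
    """

    fg_sites: list
    bg_chunks: list
    L: int

    def __post_init__(self) -> None:
        for s in self.fg_sites:
            if s.length != self.L:
                raise ValueError(f"foreground site {s.id!r} has length {s.length}, expected {self.L}")

    def to_labeled(self) -> LabeledData:
        """Window the background and assemble the full labeled data set."""
        return LabeledData.from_classes(extract_windows(self.bg_chunks, self.L), self.fg_sites)


def assemble_dataset(
    fg: TypingSequence[Sequence],
    bg: TypingSequence[Sequence],
    L: int = 16,
    chunk_len: int = 100,
) -> SiteBackgroundData:
    """Build a :class:`SiteBackgroundData` from raw foreground/background reads.

    Foreground records must be exactly ``L`` residues and free of ambiguous
    symbols; offending records are dropped with a logged warning.
    Background records are chunked into pieces of at most ``chunk_len`` bp.
    """
    sites = []
    dropped = 0
    for s in fg:
        if s.length == L and s.is_clean:
            sites.append(s)
        else:
            dropped += 1
    if dropped:
        logger.warning("assemble_dataset: dropped %d foreground records (wrong length or ambiguous)", dropped)
    chunks = chunk_sequences(bg, max_len=chunk_len)
    return SiteBackgroundData(fg_sites=sites, bg_chunks=chunks, L=L)
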