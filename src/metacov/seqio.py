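"""Reading, writing and subsampling of sequencing reads.

FASTQ is assumed to carry Phred+33 qualities (modern encoding); Phred+64
input is rejected rather than auto-detected, because a silent misdetection
would corrupt the error-mass estimate used downstream. FASTA input carries
no qualities, so error correction is unavailable for it.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
# IUPAC degeneracy codes collapsed to N (ambiguity cannot support exact matches)
_DEGENERATE = frozenset("RYSWKMBDHVU")


class ParseError(ValueError):
    """A malformed FASTA/FASTQ record."""


@dataclass
class SequenceRead:
    """One sequencing read.

    Parameters
    ----------
    id : str
        Read label (FASTA/FASTQ header up to first whitespace).
    bases : str
        Uppercase DNA over ``{A, C, G, T, N}``.
    error_probs : numpy.ndarray or None
        Per-base error probabilities in ``[0, 1]`` decoded from Phred+33
        qualities; ``None`` for FASTA input.
    source_index : int or None
        Position of the read in its source file/stream; set by
        :func:`sample_queries` so kernels can exclude self-matches.
    """

    id: str
    bases: str
    error_probs: np.ndarray | None = None
    source_index: int | None = None

    def __post_init__(self) -> None:
        if self.error_probs is not None and len(self.error_probs) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.error_probs)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadSetStats:
    """Summary of a read set: count N, total base pairs, mean length L̄."""

    n_reads: int = 0
    total_bp: int = 0

    @property
    def mean_length(self) -> float:
        return self.total_bp / self.n_reads if self.n_reads else 0.0

    def add(self, read: SequenceRead) -> None:
        self.n_reads += 1
        self.total_bp += len(read)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open plain or gzip text transparently by file suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_bases(raw: str, record_id: str) -> str:
    seq = raw.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    cleaned = []
    n_degenerate = 0
    for ch in seq:
        if ch in _VALID_BASES:
            cleaned.append(ch)
        elif ch in _DEGENERATE:
            cleaned.append("N")
            n_degenerate += 1
        else:
            raise ParseError(f"record {record_id!r}: invalid sequence character {ch!r}")
    logger.warning(
        "record %r: %d degenerate IUPAC bases mapped to N", record_id, n_degenerate
    )
    return "".join(cleaned)


def phred_to_error_probs(quality: str) -> np.ndarray:
    """Decode a Phred+33 quality string to per-base error probabilities."""
    scores = np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(float) - 33.0
    if scores.size and scores.min() < 0:
        raise ParseError("quality character below '!' (not Phred+33)")
    return 10.0 ** (-scores / 10.0)


def error_probs_to_phred(error_probs: np.ndarray) -> str:
    """Inverse of :func:`phred_to_error_probs` (rounded to integer scores)."""
    with np.errstate(divide="ignore"):
        scores = np.rint(-10.0 * np.log10(np.maximum(error_probs, 1e-30)))
    scores = np.clip(scores, 0, 93).astype(np.uint8) + 33
    return scores.tobytes().decode("ascii")


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream reads from a (possibly gzipped) 4-line FASTQ file.

    Yields reads in file order with Phred+33 qualities decoded to error
    probabilities. Raises :class:`ParseError` naming the record index on
    malformed records.
    """
    with _open_text(path) as handle:
        index = 0
        try:
            for title, seq, quality in FastqGeneralIterator(handle):
                rid = title.split()[0] if title else f"record_{index}"
                if len(seq) != len(quality):
                    raise ParseError(
                        f"FASTQ record {index} ({rid!r}): sequence length "
                        f"{len(seq)} != quality length {len(quality)}"
                    )
                yield SequenceRead(
                    id=rid,
                    bases=_clean_bases(seq, rid),
                    error_probs=phred_to_error_probs(quality),
                )
                index += 1
        except ValueError as exc:  # Biopython signals structural problems
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"FASTQ record {index}: {exc}") from exc


def read_fasta(path: str | Path) -> Iterator[SequenceRead]:
    """Stream reads from a (possibly gzipped, possibly line-wrapped) FASTA file.

    Records with empty sequences are skipped with a warning; degenerate
    IUPAC codes are mapped to N.
    """
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq)
            if not seq:
                logger.warning("record %r: empty sequence, skipped", record.id)
                continue
            yield SequenceRead(id=record.id, bases=_clean_bases(seq, record.id))


def read_sequences(path: str | Path) -> Iterator[SequenceRead]:
    """Dispatch to FASTQ/FASTA by suffix (.fq/.fastq vs .fa/.fasta/.fna)."""
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return read_fastq(path)
    if name.endswith((".fa", ".fasta", ".fna")):
        return read_fasta(path)
    raise ValueError(f"cannot infer sequence format from file name {name!r}")


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            if read.error_probs is None:
                raise ValueError(f"read {read.id!r} has no qualities; cannot write FASTQ")
            quality = error_probs_to_phred(read.error_probs)
            handle.write(f"@{read.id}\n{read.bases}\n+\n{quality}\n")


def write_fasta(reads: Iterable[SequenceRead], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(f">{read.id}\n")
            for i in range(0, len(read.bases), width):
                handle.write(read.bases[i : i + width] + "\n")


def collect(reads: Iterable[SequenceRead]) -> tuple[list[SequenceRead], ReadSetStats]:
    """Materialize a read stream, tagging source indices and accumulating stats."""
    stats = ReadSetStats()
    out: list[SequenceRead] = []
    for i, read in enumerate(reads):
        read.source_index = i
        stats.add(read)
        out.append(read)
    return out, stats


def sample_queries(
    reads: Sequence[SequenceRead], q_target: int, seed: int
) -> list[SequenceRead]:
    """Draw a uniform random subset of ``min(q_target, N)`` reads without
    replacement.

    Deterministic for a given seed. Sampled reads carry their source index
    so kernels can exclude the query's own occurrence from match counts.
    """
    if q_target < 1:
        raise ValueError(f"q_target must be >= 1, got {q_target}")
    rng = np.random.default_rng(seed)
    n = len(reads)
    if q_target >= n:
        chosen = np.arange(n)
    else:
        chosen = rng.choice(n, size=q_target, replace=False)
    out = []
    for i in chosen:
        read = reads[int(i)]
        if read.source_index is None:
            read.source_index = int(i)
        out.append(read)
    return out
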