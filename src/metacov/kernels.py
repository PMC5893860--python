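"""Redundancy kernels: per-query match counting across a read set.

Two kernels estimate, for each query read, how many times it is "seen
again" in the dataset:

* **k-mer kernel** — one target k-mer taken from the 5' end of each query
  read; a match is an exact occurrence of that k-mer (or its reverse
  complement) at any position of any dataset read. Runtime is linear in
  total dataset size and independent of the number of queries. Sequencing
  errors in query k-mers are compensated by subtracting E, the expected
  number of erroneous query k-mers, from the zero-match tally.
* **alignment kernel** — a query matches a dataset read if some ungapped
  offset (either strand) overlaps at least ``min_overlap`` of the query
  length with identity over the overlap at least ``min_identity``.

Matching is exact on {A, C, G, T}; windows containing N never match.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .seqio import ReadSetStats, SequenceRead

logger = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_SENTINEL = 4  # invalidates any window covering it (also encodes N)


@dataclass(frozen=True)
class KernelConfig:
    """Settings shared by both kernels.

    ``transform_factor`` multiplies raw match counts before rarefaction
    (redundancy-to-coverage transformation; identity by default).
    ``error_correction`` applies only to the k-mer kernel with quality
    data; it is forced off for FASTA input.
    """

    kernel: str = "kmer"  # "kmer" | "alignment"
    k: int = 24
    min_identity: float = 0.95
    min_overlap: float = 0.50
    transform_factor: float = 1.0
    error_correction: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("kmer", "alignment"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not 1 <= self.k <= 32:
            raise ValueError(f"k must be in [1, 32], got {self.k}")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_overlap <= 1:
            raise ValueError("min_overlap must be in (0, 1]")
        if self.transform_factor <= 0:
            raise ValueError("transform_factor must be positive")


@dataclass
class MatchProfile:
    """Per-query redundancy counts plus effective-size bookkeeping.

    ``counts[i]`` is the number of matches for query i (self occurrence
    excluded). ``error_mass`` is E, the expected number of query k-mers
    containing at least one sequencing error; :func:`apply_error_correction`
    folds it into the effective tallies.
    """

    counts: np.ndarray
    n_queries_effective: float
    n_zero_effective: float
    effective_positions: float
    error_mass: float
    stats: ReadSetStats

    @property
    def n_queries_raw(self) -> int:
        return int(self.counts.size)

    @property
    def n_zero_raw(self) -> int:
        return int(np.count_nonzero(self.counts == 0))


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_code(kmer: str) -> int:
    code = 0
    for base in _encode(kmer):
        if base == _SENTINEL:
            raise ValueError("k-mer contains N")
        code = code * 4 + int(base)
    return code


def _revcomp_code(code: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = out * 4 + (3 - code % 4)
        code //= 4
    return out


def extract_query_kmer(read: SequenceRead, k: int) -> str | None:
    """Target k-mer from the 5' end of a read, or ``None`` if ineligible.

    A read is ineligible when shorter than k or when its 5' window
    contains an N (ambiguity cannot support perfect matches).
    """
    if len(read.bases) < k:
        return None
    window = read.bases[:k]
    if "N" in window:
        return None
    return window


@dataclass
class QueryKmer:
    kmer: str
    source_index: int
    read: SequenceRead


def select_query_kmers(
    reads: Sequence[SequenceRead], q_target: int, k: int, seed: int
) -> list[QueryKmer]:
    """Sample query k-mers, redrawing past ineligible reads.

    Walks a seeded random permutation of the read set and keeps the first
    ``q_target`` eligible 5'-end k-mers, so the realized query count stays
    at ``q_target`` whenever enough eligible reads exist.
    """
    if q_target < 1:
        raise ValueError("q_target must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    queries: list[QueryKmer] = []
    for idx in order:
        read = reads[int(idx)]
        kmer = extract_query_kmer(read, k)
        if kmer is None:
            continue
        source = read.source_index if read.source_index is not None else int(idx)
        queries.append(QueryKmer(kmer=kmer, source_index=source, read=read))
        if len(queries) == q_target:
            break
    return queries


def _window_codes(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Polynomial codes of all length-k windows and their validity mask."""
    n_win = values.size - k + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n_win, dtype=np.int64)
    clean = np.where(values == _SENTINEL, 0, values)
    for j in range(k):
        codes = codes * 4 + clean[j : j + n_win]
    bad = np.concatenate(([0], np.cumsum(values == _SENTINEL)))
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


def count_kmer_matches(
    dataset: Iterable[SequenceRead],
    queries: Sequence[QueryKmer],
    k: int,
    chunk_reads: int = 100_000,
) -> MatchProfile:
    """Count occurrences of each query k-mer (or its reverse complement)
    across every window of every dataset read.

    The dataset is scanned once in chunks; per-chunk windows are matched
    against a sorted table of query codes, so runtime is proportional to
    dataset size and independent of the number of queries. The query's own
    source occurrence (5' window of its source read) is excluded. A window
    equal to both a query k-mer and its reverse complement (palindrome)
    counts once per position.
    """
    if any(len(q.kmer) != k for q in queries):
        raise ValueError("query k-mer length differs from k")

    n_q = len(queries)
    # (code, query) pairs; palindromes deduplicated so each position counts once
    pair_codes: list[int] = []
    pair_query: list[int] = []
    for i, q in enumerate(queries):
        fwd = _kmer_code(q.kmer)
        rev = _revcomp_code(fwd, k)
        pair_codes.append(fwd)
        pair_query.append(i)
        if rev != fwd:
            pair_codes.append(rev)
            pair_query.append(i)
    pair_codes_arr = np.asarray(pair_codes, dtype=np.int64)
    pair_query_arr = np.asarray(pair_query, dtype=np.int64)
    table, inverse = np.unique(pair_codes_arr, return_inverse=True)

    by_source: dict[int, list[int]] = {}
    for i, q in enumerate(queries):
        by_source.setdefault(q.source_index, []).append(i)

    counts = np.zeros(n_q, dtype=np.int64)
    stats = ReadSetStats()
    effective_positions = 0
    slot_hits = np.zeros(table.size, dtype=np.int64)

    def flush(values: np.ndarray) -> None:
        codes, valid = _window_codes(values, k)
        codes = codes[valid]
        if codes.size == 0:
            return
        pos = np.searchsorted(table, codes)
        pos[pos == table.size] = 0
        hit = table[pos] == codes
        if hit.any():
            np.add.at(slot_hits, pos[hit], 1)

    buffer: list[np.ndarray] = []
    buffered = 0
    read_index = 0
    for read in dataset:
        idx = read.source_index if read.source_index is not None else read_index
        read_index += 1
        stats.add(read)
        effective_positions += max(len(read.bases) - k + 1, 0)
        values = _encode(read.bases)
        # self-match: query's 5' window in its own source read
        for qi in by_source.get(idx, ()):
            if len(read.bases) >= k:
                window = read.bases[:k]
                if "N" not in window and window in (
                    queries[qi].kmer,
                    reverse_complement(queries[qi].kmer),
                ):
                    counts[qi] -= 1
        buffer.append(values)
        buffer.append(np.array([_SENTINEL], dtype=np.int64))
        buffered += 1
        if buffered >= chunk_reads:
            flush(np.concatenate(buffer))
            buffer, buffered = [], 0
    if buffer:
        flush(np.concatenate(buffer))

    # distribute per-code hit totals back to the queries sharing each code
    counts += np.bincount(
        pair_query_arr, weights=slot_hits[inverse].astype(float), minlength=n_q
    ).astype(np.int64)
    if (counts < 0).any():
        raise AssertionError("negative match count after self-exclusion")

    return MatchProfile(
        counts=counts,
        n_queries_effective=float(n_q),
        n_zero_effective=float(np.count_nonzero(counts == 0)),
        effective_positions=float(effective_positions),
        error_mass=0.0,
        stats=stats,
    )


def expected_error_kmers(queries: Sequence[QueryKmer], k: int) -> float:
    """E, the expected number of query k-mers containing >= 1 sequencing error.

    ``E = Σ_i [1 − Π_j (1 − e_ij)]`` over the same 5' windows used as
    queries. Returns 0 when reads carry no qualities (FASTA input).
    """
    total = 0.0
    for q in queries:
        probs = q.read.error_probs
        if probs is None:
            continue
        total += 1.0 - float(np.prod(1.0 - np.asarray(probs[:k], dtype=float)))
    return total


def apply_error_correction(profile: MatchProfile, error_mass: float) -> MatchProfile:
    """Remove E expected erroneous k-mers from the zero-match tally.

    Removal is fractional (expected-value) and deterministic: the
    effective zero count and query count drop by min(E, raw zeros), and
    the effective dataset size drops by E·(L̄ − k + 1) windows. E larger
    than the raw zero tally clamps with a warning.
    """
    if error_mass < 0:
        raise ValueError("error mass must be >= 0")
    n_zero_raw = profile.n_zero_raw
    removed = min(error_mass, float(n_zero_raw))
    if error_mass > n_zero_raw:
        logger.warning(
            "error mass E=%.2f exceeds zero-match tally %d; clamping",
            error_mass,
            n_zero_raw,
        )
    stats = profile.stats
    # mean testable windows per read: effective_positions / N == L̄ − k + 1
    mean_windows = profile.effective_positions / stats.n_reads if stats.n_reads else 0.0
    return replace(
        profile,
        n_zero_effective=float(n_zero_raw) - removed,
        n_queries_effective=float(profile.n_queries_raw) - removed,
        effective_positions=max(
            profile.effective_positions - error_mass * mean_windows, 0.0
        ),
        error_mass=error_mass,
    )


def align_ungapped(
    query: str, subject: str, config: KernelConfig
) -> bool:
    """True iff some ungapped offset of subject (either strand) against
    query overlaps >= ``min_overlap``·len(query) with identity over the
    overlap >= ``min_identity``. N matches nothing.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    q = _encode(query)
    min_cols = int(np.ceil(config.min_overlap * len(query)))
    for strand in (subject, reverse_complement(subject)):
        s = _encode(strand)
        if _scan_offsets(q, s, min_cols, config.min_identity):
            return True
    return False


def _scan_offsets(q: np.ndarray, s: np.ndarray, min_cols: int, min_identity: float) -> bool:
    lq, ls = q.size, s.size
    for offset in range(-(ls - 1), lq):
        lo = max(0, offset)
        hi = min(lq, offset + ls)
        overlap = hi - lo
        if overlap < min_cols:
            continue
        qs = q[lo:hi]
        ss = s[lo - offset : hi - offset]
        matches = int(np.count_nonzero((qs == ss) & (qs != _SENTINEL)))
        if matches / overlap >= min_identity:
            return True
    return False


def count_alignment_matches(
    dataset: Iterable[SequenceRead],
    queries: Sequence[SequenceRead],
    config: KernelConfig,
) -> MatchProfile:
    """Count, per query read, the dataset reads (excluding itself) that
    align ungapped at the configured identity/overlap thresholds.

    Runtime is proportional to N·Q·L²; a vectorized equal-length fast path
    compares each query against all equal-length reads per offset at once.
    """
    reads = list(dataset)
    stats = ReadSetStats()
    encoded = []
    for i, read in enumerate(reads):
        if read.source_index is None:
            read.source_index = i
        stats.add(read)
        encoded.append(_encode(read.bases))

    lengths = np.array([len(r.bases) for r in reads])
    uniform = lengths.size > 0 and (lengths == lengths[0]).all()
    counts = np.zeros(len(queries), dtype=np.int64)

    if uniform:
        mat = np.vstack(encoded).astype(np.uint8)
        rc_mat = np.ascontiguousarray(
            np.where(mat == _SENTINEL, _SENTINEL, 3 - mat)[:, ::-1]
        )
        for qi, query in enumerate(queries):
            counts[qi] = _count_uniform(
                _encode(query.bases).astype(np.uint8),
                mat,
                rc_mat,
                query.source_index,
                config,
            )
    else:
        for qi, query in enumerate(queries):
            m = 0
            for read in reads:
                if read.source_index == query.source_index:
                    continue
                if align_ungapped(query.bases, read.bases, config):
                    m += 1
            counts[qi] = m

    return MatchProfile(
        counts=counts,
        n_queries_effective=float(len(queries)),
        n_zero_effective=float(np.count_nonzero(counts == 0)),
        effective_positions=float(stats.total_bp),
        error_mass=0.0,
        stats=stats,
    )


def _count_uniform(
    q: np.ndarray,
    mat: np.ndarray,
    rc_mat: np.ndarray,
    self_index: int | None,
    config: KernelConfig,
) -> int:
    lq = q.size
    ls = mat.shape[1]
    min_cols = int(np.ceil(config.min_overlap * lq))
    offsets = [
        o
        for o in range(-(ls - 1), lq)
        if min(lq, o + ls) - max(0, o) >= min_cols
    ]
    # high-overlap offsets first: most matches found early, shrinking the
    # still-unmatched subject set scanned at later offsets
    offsets.sort(key=lambda o: -(min(lq, o + ls) - max(0, o)))
    matched = np.zeros(mat.shape[0], dtype=bool)
    remaining = np.arange(mat.shape[0])
    sub_mat, sub_rc = mat, rc_mat
    for strand_idx in (0, 1):
        for offset in offsets:
            if remaining.size == 0:
                break
            lo = max(0, offset)
            hi = min(lq, offset + ls)
            overlap = hi - lo
            qs = q[lo:hi]
            strand = sub_mat if strand_idx == 0 else sub_rc
            ss = strand[:, lo - offset : hi - offset]
            hits = ((ss == qs) & (qs != _SENTINEL)).sum(axis=1)
            new = hits >= math.ceil(config.min_identity * overlap - 1e-9)
            if new.any():
                matched[remaining[new]] = True
                keep = ~new
                remaining = remaining[keep]
                sub_mat = sub_mat[keep]
                sub_rc = sub_rc[keep]
    if self_index is not None and 0 <= self_index < matched.size:
        matched[self_index] = False
    return int(np.count_nonzero(matched))
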