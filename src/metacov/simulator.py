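"""Synthetic metagenome communities with a closed-form coverage oracle.

Emulates multi-genome communities: random genomes with lognormal cell
abundances, reads sampled proportionally to each genome's DNA fraction,
uniform start and strand, i.i.d. substitution errors, constant Phred
quality. Because genomes are uniform-random DNA (no repeats, no shared
k-mers between genomes), the abundance-weighted average coverage of a
simulated read set has the exact Lander-Waterman/Poisson form used as
the oracle here — which also means the k-mer and alignment kernels agree
more closely on these data than on real metagenomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .seqio import SequenceRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class Community:
    """Simulated community: genome sequences with abundances.

    ``dna_fractions[g]`` = a_g·G_g / Σ_h a_h·G_h is the probability a
    random sequenced base originates from genome g.
    """

    genomes: list[str]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.genomes) != self.abundances.size:
            raise ValueError("one abundance per genome required")
        if np.any(self.abundances <= 0):
            raise ValueError("abundances must be positive")

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(g) for g in self.genomes], dtype=float)

    @property
    def dna_fractions(self) -> np.ndarray:
        mass = self.abundances * self.sizes
        return mass / mass.sum()


def make_community(
    n_genomes: int = 20,
    size_range_bp: tuple[int, int] = (20_000, 100_000),
    abundance_sigma: float = 1.0,
    seed: int = 0,
) -> Community:
    """Random community: i.i.d. uniform DNA genomes with sizes uniform on
    ``size_range_bp`` and lognormal(0, ``abundance_sigma``) abundances.
    Deterministic for a given seed.
    """
    if n_genomes < 1:
        raise ValueError("need at least one genome")
    lo, hi = size_range_bp
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid genome size range {size_range_bp}")
    rng = np.random.default_rng(seed)
    sizes = rng.integers(lo, hi + 1, size=n_genomes)
    genomes = [
        _BASES[rng.integers(0, 4, size=int(size))].tobytes().decode("ascii")
        for size in sizes
    ]
    abundances = (
        np.ones(n_genomes)
        if abundance_sigma == 0
        else rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_genomes)
    )
    return Community(genomes=genomes, abundances=abundances)


def simulate_reads(
    community: Community,
    n_reads: int,
    read_len: int = 101,
    error_rate: float = 0.0,
    quality_q: int | None = None,
    seed: int = 0,
) -> Iterator[SequenceRead]:
    """Draw reads from the community with substitution errors.

    Genome chosen proportionally to DNA fraction, start uniform, strand
    uniform; substitutions i.i.d. at ``error_rate`` to a uniformly chosen
    different base. The quality string is constant at ``quality_q``
    (default: the Phred score matching ``error_rate``, Q40 if error-free).
    Read ids encode genome, start, strand and error count for truth
    tracking: ``read_<i>|g=<g>|s=<start>|st=<+/−>|err=<n>``.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if any(len(g) < read_len for g in community.genomes):
        raise ValueError("read_len exceeds the smallest genome")
    if quality_q is None:
        quality_q = 40 if error_rate == 0 else int(round(-10 * math.log10(error_rate)))
    error_prob = 10.0 ** (-quality_q / 10.0)

    rng = np.random.default_rng(seed)
    fractions = community.dna_fractions
    for i in range(n_reads):
        g = int(rng.choice(fractions.size, p=fractions))
        genome = community.genomes[g]
        start = int(rng.integers(0, len(genome) - read_len + 1))
        fragment = genome[start : start + read_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = "".join(_COMP[b] for b in reversed(fragment))
        n_errors = 0
        if error_rate > 0:
            bases = np.frombuffer(fragment.encode("ascii"), dtype=np.uint8).copy()
            hit = np.nonzero(rng.random(read_len) < error_rate)[0]
            for j in hit:
                current = bases[j]
                choices = _BASES[_BASES != current]
                bases[j] = choices[rng.integers(0, 3)]
            n_errors = int(hit.size)
            fragment = bases.tobytes().decode("ascii")
        yield SequenceRead(
            id=f"read_{i}|g={g}|s={start}|st={strand}|err={n_errors}",
            bases=fragment,
            error_probs=np.full(read_len, error_prob),
            source_index=i,
        )


def inject_errors(
    reads: Sequence[SequenceRead], error_rate: float, seed: int = 0
) -> list[SequenceRead]:
    """Copy reads with i.i.d. substitution errors at ``error_rate``.

    Quality strings are set to the constant Phred score matching the
    injection rate, so the expected-error mass computed from qualities is
    accurate. Used for error-correction experiments where only the query
    reads carry (extra) errors, the dataset staying clean.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    quality_q = 40 if error_rate == 0 else int(round(-10 * math.log10(error_rate)))
    error_prob = 10.0 ** (-quality_q / 10.0)
    rng = np.random.default_rng(seed)
    out = []
    for read in reads:
        bases = np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8).copy()
        if error_rate > 0:
            hit = np.nonzero(rng.random(bases.size) < error_rate)[0]
            for j in hit:
                if chr(bases[j]) not in "ACGT":
                    continue
                choices = _BASES[_BASES != bases[j]]
                bases[j] = choices[rng.integers(0, 3)]
        out.append(
            SequenceRead(
                id=read.id,
                bases=bases.tobytes().decode("ascii"),
                error_probs=np.full(bases.size, error_prob),
                source_index=read.source_index,
            )
        )
    return out


def expected_poisson_coverage(
    community: Community, n_reads: int, read_len: int
) -> float:
    """Analytic abundance-weighted coverage oracle.

    Each genome's bases are covered Poisson with expected depth
    d_g = n_reads·f_g·read_len/G_g; the community coverage is the
    DNA-fraction-weighted probability a random base is sequenced:
    Σ_g f_g·(1 − e^(−d_g)).
    """
    fractions = community.dna_fractions
    sizes = community.sizes
    depth = n_reads * fractions * read_len / sizes
    return float(np.sum(fractions * -np.expm1(-depth)))


def reads_for_target_coverage(
    community: Community, target: float, read_len: int
) -> int:
    """Invert the Poisson oracle: smallest read count whose expected
    coverage reaches ``target``."""
    if not 0 < target < 1:
        raise ValueError("target must be in (0, 1)")
    lo, hi = 1, 2
    while expected_poisson_coverage(community, hi, read_len) < target:
        hi *= 2
        if hi > 10**10:
            raise RuntimeError("target coverage unreachable")
    while lo < hi:
        mid = (lo + hi) // 2
        if expected_poisson_coverage(community, mid, read_len) < target:
            lo = mid + 1
        else:
            hi = mid
    return lo


def write_truth_table(reads: Sequence[SequenceRead], path: str | Path) -> None:
    """Truth TSV (read_id, genome, start, strand, n_errors) parsed from ids."""
    with open(path, "w") as handle:
        handle.write("read_id\tgenome\tstart\tstrand\tn_errors\n")
        for read in reads:
            label, *fields = read.id.split("|")
            values = dict(f.split("=", 1) for f in fields)
            handle.write(
                f"{label}\t{values['g']}\t{values['s']}\t{values['st']}\t{values['err']}\n"
            )
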