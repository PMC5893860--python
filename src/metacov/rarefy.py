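"""Rarefied coverage curves from redundancy profiles.

A query read is "covered" at a given sequencing effort if at least one of
its matches survives random subsampling of the dataset to that effort.
By the Turing-Good principle the expected covered fraction of queries
estimates the abundance-weighted average coverage of the community at
that effort. Subsampling is evaluated in closed form: a query with m
matches is missed by a subsample of fraction p with probability
(1 − p)^m, so

    Ĉ(p) = 1 − [Σ_i (1 − p)^{m_i} − E] / Q'

where E is the expected erroneous-query mass and Q' the error-corrected
query count. The per-point SD uses the independent-Bernoulli
approximation. A Monte-Carlo estimator over explicit binomial subsamples
is retained as a cross-check.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .kernels import KernelConfig, MatchProfile

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"

_MANDATORY_HEADERS = (
    "version",
    "kernel",
    "k",
    "reads",
    "bases",
    "mean_length",
    "queries_effective",
    "error_mass",
    "seed",
)


class FormatError(ValueError):
    """Malformed curve file."""


@dataclass
class RarefactionCurve:
    """Coverage-vs-effort points plus run metadata.

    ``efforts_bp`` are strictly increasing sequencing efforts on the raw
    base-pair scale; ``coverage_mean`` the estimated abundance-weighted
    coverage in [0, 1]; ``coverage_sd`` its Bernoulli-approximation SD.
    """

    efforts_bp: np.ndarray
    coverage_mean: np.ndarray
    coverage_sd: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.efforts_bp = np.asarray(self.efforts_bp, dtype=float)
        self.coverage_mean = np.asarray(self.coverage_mean, dtype=float)
        self.coverage_sd = np.asarray(self.coverage_sd, dtype=float)
        if not (
            self.efforts_bp.size == self.coverage_mean.size == self.coverage_sd.size
        ):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.efforts_bp) <= 0):
            raise ValueError("efforts must be strictly increasing")

    def __len__(self) -> int:
        return int(self.efforts_bp.size)

    @property
    def total_bp(self) -> float:
        """Full raw sequencing effort of the dataset the curve came from."""
        return float(self.metadata.get("bases", self.efforts_bp[-1]))


def logarithmic_efforts(n_reads: int, density_factor: float = 0.7) -> list[int]:
    """Logarithmic series of subsample sizes.

    Starting at ``n_reads``, each size is ``floor(previous × density_factor)``
    until fewer than two reads remain; duplicates are dropped and the
    series is returned ascending.
    """
    if n_reads < 2:
        raise ValueError(f"need at least 2 reads, got {n_reads}")
    if not 0 < density_factor < 1:
        raise ValueError(f"density_factor must be in (0, 1), got {density_factor}")
    sizes = []
    size = n_reads
    while size >= 2:
        sizes.append(size)
        nxt = math.floor(size * density_factor)
        if nxt == size:  # guard against factor ~1 stalls
            nxt = size - 1
        size = nxt
    return sorted(set(sizes))


def coverage_at_effort(profile: MatchProfile, p: float) -> tuple[float, float]:
    """Closed-form (mean, sd) coverage at subsample fraction ``p``."""
    if not 0 < p <= 1:
        raise ValueError(f"subsample fraction must be in (0, 1], got {p}")
    if profile.n_queries_effective < 1:
        raise ValueError("profile has no effective queries")
    miss = (1.0 - p) ** profile.counts.astype(float)
    q_eff = profile.n_queries_effective
    mean = 1.0 - (float(miss.sum()) - profile.error_mass) / q_eff
    if mean < 0 or mean > 1:
        logger.warning("coverage %.4f at p=%.4g clamped to [0, 1]", mean, p)
        mean = min(max(mean, 0.0), 1.0)
    sd = float(np.sqrt(np.sum(miss * (1.0 - miss)))) / q_eff
    return mean, sd


def coverage_at_effort_mc(
    profile: MatchProfile, p: float, n_replicates: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo coverage at fraction ``p``: each replicate binomially
    subsamples every query's matches and scores it covered if any survive.
    Cross-check for :func:`coverage_at_effort`; same error-mass handling.
    """
    if not 0 < p <= 1:
        raise ValueError(f"subsample fraction must be in (0, 1], got {p}")
    rng = np.random.default_rng(seed)
    counts = profile.counts
    q_eff = profile.n_queries_effective
    covered = np.empty(n_replicates)
    for r in range(n_replicates):
        survivors = rng.binomial(counts, p)
        n_missed = float(np.count_nonzero(survivors == 0))
        covered[r] = 1.0 - (n_missed - profile.error_mass) / q_eff
    covered = np.clip(covered, 0.0, 1.0)
    return float(covered.mean()), float(covered.std(ddof=1))


def build_curve(
    profile: MatchProfile,
    config: KernelConfig,
    density_factor: float = 0.7,
    seed: int | None = None,
) -> RarefactionCurve:
    """Rarefaction curve over a logarithmic effort series.

    Efforts are expressed on the raw base-pair scale of the dataset. The
    k-mer kernel only probes L − k + 1 of the L windows a read could
    cover, so the effort probed at subsample fraction p is
    p · total_bp · (L̄ − k + 1)/L̄; the alignment kernel probes the full
    read span and needs no correction.
    """
    stats = profile.stats
    if stats.n_reads < 2:
        sizes = [stats.n_reads] if stats.n_reads else []
    else:
        sizes = logarithmic_efforts(stats.n_reads, density_factor)
    if config.kernel == "kmer" and stats.mean_length > 0:
        scale = max(stats.mean_length - config.k + 1, 0.0) / stats.mean_length
    else:
        scale = 1.0

    efforts, means, sds = [], [], []
    if config.transform_factor != 1.0:
        from dataclasses import replace

        profile = replace(
            profile, counts=profile.counts.astype(float) * config.transform_factor
        )
    for size in sizes:
        p = size / stats.n_reads
        mean, sd = coverage_at_effort(profile, p)
        efforts.append(p * stats.total_bp * scale)
        means.append(mean)
        sds.append(sd)

    metadata = {
        "version": FORMAT_VERSION,
        "kernel": config.kernel,
        "k": config.k,
        "reads": stats.n_reads,
        "bases": stats.total_bp,
        "mean_length": stats.mean_length,
        "queries_effective": profile.n_queries_effective,
        "error_mass": profile.error_mass,
        "seed": seed if seed is not None else "",
    }
    return RarefactionCurve(
        efforts_bp=np.array(efforts),
        coverage_mean=np.array(means),
        coverage_sd=np.array(sds),
        metadata=metadata,
    )


def write_npo(curve: RarefactionCurve, path: str | Path) -> None:
    """Serialize a curve as TSV with ``# key<TAB>value`` header lines."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        meta = dict(curve.metadata)
        meta.setdefault("version", FORMAT_VERSION)
        for key in _MANDATORY_HEADERS:
            handle.write(f"# {key}\t{meta.get(key, '')}\n")
        for key in sorted(set(meta) - set(_MANDATORY_HEADERS)):
            handle.write(f"# {key}\t{meta[key]}\n")
        for effort, mean, sd in zip(
            curve.efforts_bp, curve.coverage_mean, curve.coverage_sd
        ):
            handle.write(f"{effort:.17g}\t{mean:.17g}\t{sd:.17g}\n")


_INT_KEYS = {"k", "reads"}
_FLOAT_KEYS = {"bases", "mean_length", "queries_effective", "error_mass"}


def read_npo(path: str | Path) -> RarefactionCurve:
    """Parse a curve file written by :func:`write_npo`."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    metadata: dict = {}
    efforts, means, sds = [], [], []
    with opener(path, "rt") as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "\t" not in body:
                    raise FormatError(f"line {line_no}: malformed header {line!r}")
                key, value = body.split("\t", 1)
                if key in _INT_KEYS:
                    value = int(value)
                elif key in _FLOAT_KEYS:
                    value = float(value)
                metadata[key] = value
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"line {line_no}: expected 3 columns, got {len(fields)}")
            efforts.append(float(fields[0]))
            means.append(float(fields[1]))
            sds.append(float(fields[2]))
    for key in _MANDATORY_HEADERS:
        if key not in metadata:
            raise FormatError(f"missing header: {key}")
    return RarefactionCurve(
        efforts_bp=np.array(efforts),
        coverage_mean=np.array(means),
        coverage_sd=np.array(sds),
        metadata=metadata,
    )
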