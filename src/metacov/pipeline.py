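"""End-to-end coverage estimation: reads -> redundancy -> curve -> model."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from . import kernels, model, rarefy, seqio

logger = logging.getLogger(__name__)

DEFAULT_QUERIES_KMER = 10_000
DEFAULT_QUERIES_ALIGNMENT = 1_000


def default_queries(kernel: str) -> int:
    """Default query count: 10,000 for the k-mer kernel (runtime does not
    depend on it), 1,000 for the quadratic alignment kernel."""
    return DEFAULT_QUERIES_KMER if kernel == "kmer" else DEFAULT_QUERIES_ALIGNMENT


@dataclass
class EstimationResult:
    profile: kernels.MatchProfile
    curve: rarefy.RarefactionCurve
    model: model.CoverageModel | None
    summary: dict


def estimate_from_reads(
    reads: Sequence[seqio.SequenceRead],
    config: kernels.KernelConfig | None = None,
    q_target: int | None = None,
    density_factor: float = 0.7,
    seed: int = 0,
    queries: Sequence[seqio.SequenceRead] | None = None,
    fit: bool = True,
) -> EstimationResult:
    """Run the full estimation on an in-memory read set.

    ``queries`` overrides query sampling (e.g. for error-injection
    experiments where modified copies of dataset reads serve as queries);
    otherwise ``q_target`` reads are sampled with the given seed.
    """
    config = config or kernels.KernelConfig()
    reads, stats = seqio.collect(iter(reads)) if reads and reads[0].source_index is None else (list(reads), None)
    if q_target is None:
        q_target = default_queries(config.kernel)

    if config.kernel == "kmer":
        if queries is None:
            query_kmers = kernels.select_query_kmers(reads, q_target, config.k, seed)
        else:
            query_kmers = []
            for read in queries:
                kmer = kernels.extract_query_kmer(read, config.k)
                if kmer is None:
                    continue
                query_kmers.append(
                    kernels.QueryKmer(
                        kmer=kmer, source_index=read.source_index, read=read
                    )
                )
        profile = kernels.count_kmer_matches(reads, query_kmers, config.k)
        correct = config.error_correction and all(
            q.read.error_probs is not None for q in query_kmers
        )
        if config.error_correction and not correct:
            logger.warning("error correction disabled (no qualities)")
        if correct:
            e_mass = kernels.expected_error_kmers(query_kmers, config.k)
            profile = kernels.apply_error_correction(profile, e_mass)
        logger.info(
            "kmer kernel: %d queries, E=%.2f, %d reads",
            len(query_kmers),
            profile.error_mass,
            profile.stats.n_reads,
        )
    else:
        query_reads = (
            list(queries)
            if queries is not None
            else seqio.sample_queries(reads, q_target, seed)
        )
        profile = kernels.count_alignment_matches(reads, query_reads, config)
        logger.info(
            "alignment kernel: %d queries, %d reads",
            len(query_reads),
            profile.stats.n_reads,
        )

    curve = rarefy.build_curve(profile, config, density_factor, seed=seed)

    fitted = None
    summary: dict = {}
    if fit:
        try:
            fitted = model.fit_model(curve)
            summary = fitted.summary(curve)
        except model.FitError as exc:
            logger.warning("model fit failed: %s", exc)
            summary = {"fit_error": str(exc)}
    return EstimationResult(profile=profile, curve=curve, model=fitted, summary=summary)


def estimate_from_file(
    path,
    config: kernels.KernelConfig | None = None,
    q_target: int | None = None,
    density_factor: float = 0.7,
    seed: int = 0,
    fit: bool = True,
) -> EstimationResult:
    """Run the full estimation on a FASTQ/FASTA file."""
    reads, _ = seqio.collect(seqio.read_sequences(path))
    return estimate_from_reads(
        reads,
        config=config,
        q_target=q_target,
        density_factor=density_factor,
        seed=seed,
        fit=fit,
    )
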