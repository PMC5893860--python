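"""Desk-scale validation experiments on synthetic communities.

Each experiment builds its own simulated inputs, runs the estimation
pipeline, and returns the measured quantities together with the ground
truth or reference it is compared against. They are used by the test
suite and the reproduction script; problem sizes are chosen so every
experiment runs in seconds to a few minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import kernels, model, pipeline, rarefy, simulator
from .seqio import SequenceRead, sample_queries

#: standard test community: 20 random genomes of 20-100 kbp, lognormal
#: abundances with sigma = 1, 101-bp reads
COMMUNITY_KW = dict(n_genomes=20, size_range_bp=(20_000, 100_000), abundance_sigma=1.0)
READ_LEN = 101


def _subsample_reads(reads, fraction, rng):
    idx = rng.choice(len(reads), size=int(fraction * len(reads)), replace=False)
    return [
        SequenceRead(reads[i].id, reads[i].bases, reads[i].error_probs, j)
        for j, i in enumerate(sorted(idx))
    ]


def poisson_oracle_experiment(
    seed: int,
    targets=(0.3, 0.6, 0.9),
    n_seeds: int = 3,
    q_target: int = 10_000,
) -> dict:
    """Pipeline coverage estimate vs the analytic Poisson oracle.

    For each target true coverage, simulates error-free read sets at the
    read count where the oracle hits the target, runs the k-mer kernel
    pipeline, and records the headline coverage estimate.
    """
    rows = []
    for rep in range(n_seeds):
        community = simulator.make_community(**COMMUNITY_KW, seed=seed + rep)
        for target in targets:
            n_reads = simulator.reads_for_target_coverage(community, target, READ_LEN)
            reads = list(
                simulator.simulate_reads(
                    community, n_reads, READ_LEN, error_rate=0.0, seed=seed + 100 + rep
                )
            )
            result = pipeline.estimate_from_reads(
                reads, q_target=q_target, seed=seed + 200 + rep
            )
            oracle = simulator.expected_poisson_coverage(community, n_reads, READ_LEN)
            rows.append(
                {
                    "target": target,
                    "n_reads": n_reads,
                    "oracle": oracle,
                    "estimate": result.summary["coverage"],
                    "error": result.summary["coverage"] - oracle,
                }
            )
    errors = np.array([abs(r["error"]) for r in rows])
    return {"rows": rows, "max_abs_error": float(errors.max()), "mean_abs_error": float(errors.mean())}


def error_correction_experiment(
    seed: int,
    error_rates=(0.005, 0.01),
    q_target: int = 10_000,
    full_coverage: float = 0.98,
) -> dict:
    """Effect of quality-based error correction on coverage estimates.

    Mirrors the protocol of the original correction experiment: a clean
    deeply-sequenced dataset; the selected query reads (and only those)
    receive i.i.d. substitution errors with quality strings matching the
    injection rate; the estimate with correction on should match the
    0%-error run, and with correction off it should fall below it.
    """
    community = simulator.make_community(**COMMUNITY_KW, seed=seed)
    n_reads = simulator.reads_for_target_coverage(community, full_coverage, READ_LEN)
    reads = list(
        simulator.simulate_reads(community, n_reads, READ_LEN, 0.0, seed=seed + 1)
    )
    queries = sample_queries(reads, q_target, seed=seed + 2)
    baseline = pipeline.estimate_from_reads(
        reads, queries=simulator.inject_errors(queries, 0.0, seed + 3), seed=seed
    ).summary["coverage"]
    out = {"baseline": baseline, "rates": {}}
    for rate in error_rates:
        injected = simulator.inject_errors(queries, rate, seed + 3)
        on = pipeline.estimate_from_reads(reads, queries=injected, seed=seed)
        off = pipeline.estimate_from_reads(
            reads,
            queries=injected,
            seed=seed,
            config=kernels.KernelConfig(error_correction=False),
        )
        out["rates"][rate] = {
            "corrected": on.summary["coverage"],
            "uncorrected": off.summary["coverage"],
            "corrected_dev": on.summary["coverage"] - baseline,
            "uncorrected_dev": off.summary["coverage"] - baseline,
        }
    out["max_corrected_abs_dev"] = max(
        abs(v["corrected_dev"]) for v in out["rates"].values()
    )
    return out


def parameter_recovery_experiment(seed: int, n_trials: int = 100) -> dict:
    """Nd recovery from curves generated by the gamma-CDF model itself:
    noiseless recovery of (alpha, beta) and median Nd error at 1% noise."""
    from scipy import special

    def curve_from(alpha, beta, noise_sd, rng):
        x = np.linspace(
            special.gammaincinv(alpha, 0.02) / beta,
            special.gammaincinv(alpha, 0.98) / beta,
            15,
        )
        cov = special.gammainc(alpha, beta * x)
        if noise_sd:
            cov = np.clip(cov + rng.normal(0, noise_sd, x.size), 1e-6, 1 - 1e-6)
        return rarefy.RarefactionCurve(
            efforts_bp=np.expm1(x),
            coverage_mean=cov,
            coverage_sd=np.full(x.size, max(noise_sd, 1e-3)),
        )

    rng = np.random.default_rng(seed)
    noiseless = curve_from(5.0, 0.5, 0.0, rng)
    fit = model.fit_model(noiseless)
    noiseless_rel = max(abs(fit.alpha - 5.0) / 5.0, abs(fit.beta - 0.5) / 0.5)

    rel_errors = []
    for _ in range(n_trials):
        alpha = rng.uniform(1.5, 30.0)
        beta = rng.uniform(0.3, 3.0)
        fitted = model.fit_model(curve_from(alpha, beta, 0.01, rng))
        true_nd = (alpha - 1.0) / beta
        rel_errors.append(abs(fitted.nd - true_nd) / true_nd)
    return {
        "noiseless_max_rel_error": float(noiseless_rel),
        "median_nd_rel_error": float(np.median(rel_errors)),
        "n_trials": n_trials,
    }


def nd_subsample_experiment(
    seed: int,
    fractions=(0.3, 0.1, 0.03),
    q_target: int = 3_000,
    full_coverage: float = 0.98,
) -> dict:
    """Coverage independence of Nd: re-estimating from random read
    subsamples of one deeply sequenced dataset should leave Nd stable."""
    community = simulator.make_community(**COMMUNITY_KW, seed=seed)
    n_reads = simulator.reads_for_target_coverage(community, full_coverage, READ_LEN)
    reads = list(
        simulator.simulate_reads(community, n_reads, READ_LEN, 0.0, seed=seed + 1)
    )
    rng = np.random.default_rng(seed + 2)
    nds = {}
    for fraction in fractions:
        sub = _subsample_reads(reads, fraction, rng)
        result = pipeline.estimate_from_reads(sub, q_target=q_target, seed=seed + 3)
        nds[fraction] = result.summary["nd"]
    return {"nd_by_fraction": nds, "nd_sd": float(np.std(list(nds.values())))}


def kernel_concordance_experiment(
    seed: int,
    target_coverage: float = 0.3,
    q_kmer: int = 10_000,
    q_alignment: int = 1_000,
) -> dict:
    """Coverage from the k-mer kernel vs the ungapped-alignment kernel on
    the same synthetic dataset (the k-mer estimate runs slightly lower)."""
    community = simulator.make_community(**COMMUNITY_KW, seed=seed)
    n_reads = simulator.reads_for_target_coverage(
        community, target_coverage, READ_LEN
    )
    reads = list(
        simulator.simulate_reads(community, n_reads, READ_LEN, 0.0, seed=seed + 1)
    )
    kmer = pipeline.estimate_from_reads(reads, q_target=q_kmer, seed=seed + 2)
    alignment = pipeline.estimate_from_reads(
        reads,
        q_target=q_alignment,
        seed=seed + 2,
        config=kernels.KernelConfig(kernel="alignment"),
    )
    return {
        "kmer_coverage": kmer.summary["coverage"],
        "alignment_coverage": alignment.summary["coverage"],
        "gap": kmer.summary["coverage"] - alignment.summary["coverage"],
        "n_reads": n_reads,
    }


def kmer_oracle_equivalence_experiment(seed: int, n_trials: int = 100) -> dict:
    """Fast k-mer counting vs a naive window-scan oracle on small read
    sets, and closed-form rarefaction vs Monte-Carlo subsampling."""
    from .kernels import QueryKmer, reverse_complement

    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_trials):
        n = int(rng.integers(5, 51))
        length = int(rng.integers(8, 30))
        k = int(rng.integers(4, min(length, 12)))
        reads = []
        for i in range(n):
            bases = "".join(rng.choice(list("ACGT"), size=length))
            reads.append(SequenceRead(f"r{i}", bases, source_index=i))
        queries = [
            QueryKmer(kmer=reads[int(i)].bases[:k], source_index=int(i), read=reads[int(i)])
            for i in rng.choice(n, size=min(10, n), replace=False)
        ]
        fast = kernels.count_kmer_matches(reads, queries, k).counts
        slow = []
        for q in queries:
            targets = {q.kmer, reverse_complement(q.kmer)}
            m = 0
            for read in reads:
                for off in range(length - k + 1):
                    window = read.bases[off : off + k]
                    if window in targets and not (
                        read.source_index == q.source_index and off == 0
                    ):
                        m += 1
            slow.append(m)
        mismatches += int(np.any(fast != np.array(slow)))

    # closed-form vs Monte-Carlo rarefaction
    counts = rng.poisson(1.2, size=300)
    from .seqio import ReadSetStats

    profile = kernels.MatchProfile(
        counts=counts,
        n_queries_effective=float(counts.size),
        n_zero_effective=float((counts == 0).sum()),
        effective_positions=300.0 * 78,
        error_mass=0.0,
        stats=ReadSetStats(n_reads=300, total_bp=300 * 101),
    )
    max_z = 0.0
    for p in (0.05, 0.3, 0.7):
        closed, _ = rarefy.coverage_at_effort(profile, p)
        mc_mean, mc_sd = rarefy.coverage_at_effort_mc(
            profile, p, n_replicates=2000, seed=seed
        )
        se = max(mc_sd / np.sqrt(2000), 1e-12)
        max_z = max(max_z, abs(closed - mc_mean) / se)
    return {"count_mismatch_trials": mismatches, "max_mc_z": float(max_z), "n_trials": n_trials}


def exact_estimator_values() -> dict:
    """Closed-form spot checks of the point estimators."""
    import math

    from .model import CoverageModel
    from .otu_diversity import shannon_bayes, shannon_mle, turing_good_coverage

    m11 = CoverageModel(alpha=2.0, beta=1.0, fit_sse=0.0, n_points_used=0, converged=True)
    m_alpha1 = CoverageModel(alpha=1.0, beta=1.0, fit_sse=0.0, n_points_used=0, converged=True)
    return {
        "turing_good_211": turing_good_coverage([2, 1, 1]),
        "shannon_mle_211": shannon_mle([2, 1, 1]),
        "shannon_bayes_31": shannon_bayes([3, 1]),
        "nd_alpha2_beta1": model.nd(m11),
        "model_alpha1_at_e_minus_1": model.gamma_model_coverage(math.e - 1, 1.0, 1.0),
        "projection_alpha1_at_1_minus_1_over_e": model.project_effort(
            m_alpha1, 1 - math.exp(-1)
        ),
    }
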