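import numpy as np
import pytest

import metacov as mc


@pytest.fixture(scope="session")
def community():
    """Standard 20-genome test community (sizes 20-100 kbp, lognormal sigma=1)."""
    return mc.make_community(
        n_genomes=20, size_range_bp=(20_000, 100_000), abundance_sigma=1.0, seed=7
    )


@pytest.fixture(scope="session")
def small_community():
    return mc.make_community(
        n_genomes=3, size_range_bp=(5_000, 10_000), abundance_sigma=0.5, seed=19
    )


def random_reads(n, length, seed, alphabet="ACGT"):
    """Unrelated uniform-random reads (no genome structure)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        bases = "".join(rng.choice(list(alphabet), size=length))
        out.append(mc.SequenceRead(id=f"r{i}", bases=bases, source_index=i))
    return out


def brute_force_kmer_counts(reads, queries, k):
    """Naive O(N*L*Q) window-comparison oracle for the k-mer kernel."""
    from metacov.kernels import reverse_complement

    counts = []
    for q in queries:
        targets = {q.kmer, reverse_complement(q.kmer)}
        m = 0
        for read in reads:
            for off in range(len(read.bases) - k + 1):
                window = read.bases[off : off + k]
                if "N" in window:
                    continue
                if window in targets:
                    if read.source_index == q.source_index and off == 0:
                        continue  # self occurrence
                    m += 1
        counts.append(m)
    return np.array(counts)
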