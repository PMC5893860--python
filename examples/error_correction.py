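"""Quality-based error correction of the k-mer redundancy kernel.

Sequencing errors in a query read's 5'-end k-mer almost always create a
variant seen nowhere else, inflating the zero-match tally and deflating
the coverage estimate. The expected number of such erroneous k-mers (E)
is computed from the Phred qualities and subtracted. Here errors are
injected into the query reads of a clean simulated dataset to show the
correction restoring the error-free estimate.
"""

import metacov as mc

community = mc.make_community(n_genomes=10, size_range_bp=(20_000, 60_000), seed=21)
n_reads = mc.reads_for_target_coverage(community, target=0.9, read_len=101)
reads = list(mc.simulate_reads(community, n_reads, read_len=101, seed=22))
queries = mc.sample_queries(reads, 2_000, seed=23)

clean = mc.estimate_from_reads(
    reads, queries=mc.inject_errors(queries, 0.0, seed=24), seed=25
)
print(f"0% query error           : coverage {clean.summary['coverage']:.3f}")

for rate in (0.005, 0.01):
    noisy = mc.inject_errors(queries, rate, seed=24)
    on = mc.estimate_from_reads(reads, queries=noisy, seed=25)
    off = mc.estimate_from_reads(
        reads, queries=noisy, seed=25,
        config=mc.KernelConfig(error_correction=False),
    )
    print(f"{rate:.1%} query error, corrected  : "
          f"coverage {on.summary['coverage']:.3f} (E = {on.profile.error_mass:.0f})")
    print(f"{rate:.1%} query error, uncorrected: "
          f"coverage {off.summary['coverage']:.3f}")

# With correction on, the estimates stay within ~0.02 of the clean run;
# with correction off, 1% per-base error (~21% of 24-mers hit) drags the
# estimate far below it.
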