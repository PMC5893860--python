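"""Project the sequencing effort needed to reach a target coverage.

Writes a rarefaction curve to a .npo file, reads it back, refits the
model, and inverts it at several coverage targets — the workflow for
deciding how much more sequencing a sample needs.
"""

import tempfile
from pathlib import Path

import metacov as mc

community = mc.make_community(n_genomes=10, size_range_bp=(20_000, 60_000), seed=3)
n_reads = mc.reads_for_target_coverage(community, target=0.5, read_len=101)
reads = list(mc.simulate_reads(community, n_reads, read_len=101, seed=4))
result = mc.estimate_from_reads(reads, q_target=2_000, seed=5)

with tempfile.TemporaryDirectory() as tmp:
    npo = Path(tmp) / "sample.npo"
    mc.write_npo(result.curve, npo)          # curve persists independently
    curve = mc.read_npo(npo)                 # of the fit step
    model = mc.fit_model(curve)

current = curve.total_bp
print(f"current effort   : {current / 1e6:.2f} Mbp "
      f"(model coverage {model.coverage(current):.3f})")
for target in (0.75, 0.90, 0.95, 0.99):
    lr = mc.project_effort(model, target)
    print(f"target {target:.2f} coverage -> {lr / 1e6:8.1f} Mbp "
          f"({lr / current:6.1f}x current)")

# The projection is the exact inverse of the fitted gamma CDF; required
# effort grows super-linearly as the target approaches 1.
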