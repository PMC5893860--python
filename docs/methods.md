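# Methods

## Model and rationale

### Redundancy as a coverage estimator

Let a metagenome be N single reads of mean length L̄ (total effort LR bp).
For a random query read, define redundancy as the event that the query is
observed again in the rest of the dataset. If the community's DNA is
sampled uniformly at random, the probability that a random community base
is covered by some read (the abundance-weighted average coverage) equals,
to first order, the probability that a random *read's position* is covered
by another read — which is observable. Non-redundant queries play the role
of singletons in the Turing-Good estimator: the expected fraction of
never-again-seen queries estimates the unsampled fraction of the DNA.

Two operationalizations of "seen again" are provided:

- **Alignment kernel.** Query q matches read s if some ungapped offset of
  s (or its reverse complement) against q overlaps ≥ `min_overlap`
  (default 0.50) of the query length with identity over the overlap
  ≥ `min_identity` (default 0.95). Identity is matches/overlap-columns;
  N matches nothing; all offsets on both strands are scanned. For reads of
  length L on a genome of size G, a covering read is detected with
  probability ≈ (L+1)/G per read — essentially the per-base coverage
  probability, which is what makes the redundant fraction estimate
  coverage. Cost is O(N·Q·L²) for Q queries.

- **k-mer kernel** (default). One target k-mer (default k = 24) is taken
  from the 5' end of each query read; a match is an exact occurrence of
  the k-mer or its reverse complement at any position of any read
  (palindromic windows count once per position). A single pass over the
  dataset with a sorted lookup table makes the cost O(N·L̄), independent
  of Q, so the default query count is raised to 10,000 (vs 1,000 for the
  alignment kernel). The query's own source occurrence is excluded from
  its count; queries shorter than k or with an N in the 5' window are
  ineligible and replaced by redrawing from a seeded permutation, keeping
  the realized query count at the target. k is capped at 32 so a k-mer
  packs into one 64-bit integer code.

### Effective-size correction

A read of length L can only host a k-mer match at its first L − k + 1
positions, so the k-mer kernel probes an effective dataset of
Σ(Lᵢ − k + 1) positions rather than Σ Lᵢ bases. A covering read is
detected with probability ≈ (L − k + 1)/G instead of ≈ (L + 1)/G.
Consequently the coverage measured at subsample fraction p corresponds to
a *raw-bp* effort of p · LR · (L̄ − k + 1)/L̄, and curve efforts are
recorded on that corrected scale (for L = 101, k = 24 the k-mer effort
axis is compressed by 78/101 relative to the alignment kernel's). The
headline coverage is then the fitted model evaluated at the full raw
effort LR — a short extrapolation beyond the last measured point. This
direction of the correction is fixed by the Poisson argument above and is
validated end-to-end against the simulator's analytic oracle.

### Error correction

A sequencing error inside a query k-mer almost always produces a variant
present nowhere else, inflating the zero-match tally. From the Phred
qualities of the same 5' windows, the expected number of error-containing
query k-mers is

    E = Σᵢ [1 − Πⱼ₌₁..ₖ (1 − eᵢⱼ)].

Correction removes E zero-coverage queries *fractionally* (expected-value
removal, deterministic): effective zeros become max(z − E, 0), effective
queries Q − min(E, z), and the effective dataset size drops by
E·(L̄ − k + 1) positions. E > z clamps with a warning. The assumption —
erroneous k-mers have zero matches — degrades above ~5% per-base error,
which is outside the supported regime. FASTA input has no qualities, so
correction is forced off (E = 0), and Phred+64 input is rejected rather
than auto-detected because silent misdetection would corrupt E.

### Rarefaction

Subsample sizes follow a logarithmic series: starting at N, each size is
floor(previous × density factor), default 0.7, until fewer than two reads
remain. For a query with m matches, a subsample of fraction p misses all
matches with probability (1 − p)^m, so the closed-form curve is

    Ĉ(p) = 1 − [Σᵢ (1 − p)^{mᵢ} − E] / Q',   clamped to [0, 1],

with per-point SD sqrt(Σ tᵢ(1 − tᵢ))/Q' under an independent-Bernoulli
approximation (tᵢ = (1 − p)^{mᵢ}). The closed form is the default
(deterministic, exactly testable); a Monte-Carlo subsampler with explicit
binomial draws is retained and tested to agree within Monte-Carlo error.
The SD estimator only feeds fit weights; it ignores between-query
correlation and is not a confidence interval.

### Model, Nd, projection

The curve is fitted to Ĉ(LR) = γ[α, β·ln(LR + 1)]/Γ(α) (regularized
lower incomplete gamma; natural log throughout) by weighted nonlinear
least squares in log-parameter space (Levenberg-Marquardt, tolerances
1e-10). Weights are 1/max(sd², 1e-4); points with coverage exactly 0 or 1
are demoted to the smallest interior weight so saturated tails cannot
dominate. Initialization is a fixed grid α₀ ∈ {1.5, 3, 5, 10, 20}, each
with β₀ chosen so the model median matches the curve's half-coverage
effort; the best weighted SSE wins, making the fit fully deterministic.
At least 3 points with coverage strictly inside (0, 1) are required.

The gamma mode gives the diversity index Nd = (α − 1)/β (ln-bp units),
reported as 0 with a warning when α ≤ 1. Effort projection inverts the
CDF exactly: LR* = exp(Qγ(target; α)/β) − 1; target 1.0 reports infinite
effort. The headline coverage is the model at the dataset's full raw
effort; the raw last curve point is reported alongside.

The gamma-CDF family is a smoothing approximation, not the true law of a
finite genome mixture. Two visible consequences, both quantified in the
tests: a ×10 effort rescale (a +ln 10 shift on the ln-effort axis) is
absorbed only approximately, tightening as α grows (~8% projection-ratio
deviation at α = 20, ~2% at α = 80); and fitting truncated (shallowly
subsampled) curves drifts Nd upward by a few tenths of a ln-bp unit,
while α itself varies much more — Nd is the stable summary, α and β
individually are not interpretable.

## Synthetic communities and what the tests show

`make_community` draws i.i.d. uniform-random genomes (default 20 genomes,
20–100 kbp) with lognormal(0, σ = 1) abundances; `simulate_reads` draws
101-bp reads with genome probability proportional to DNA fraction
f_g = a_g G_g / Σ a_h G_h, uniform start and strand, i.i.d. substitutions,
constant Phred quality matching the error rate, and truth-tracking ids.
The expected coverage has the exact closed form Σ_g f_g (1 − e^(−d_g))
with d_g = n f_g L / G_g, used as the oracle everywhere.

Random genomes contain no repeats, no shared sequence between genomes,
and no compositional bias. Passing tests therefore show correctness of
the estimator under its own sampling assumptions — they do not probe
repeat-induced redundancy inflation, conserved-region cross-matching (the
main reason the k-mer and alignment kernels differ more on real data than
here), GC skew, or platform-specific error profiles (indels are not
simulated). The error-correction experiments inject substitutions into
the *query reads only*, with the dataset kept clean, matching the
protocol under which the correction's zero-coverage assumption is exact.

Experiment sizes (three depths × three community seeds for the oracle
check; ~10⁴–10⁵ reads per dataset; 10,000 queries for k-mer runs, ~10³
for alignment runs; the deeply sequenced reference for the
subsample-stability experiment at 98% true coverage, mirroring a
high-coverage reference being downsampled to 30/10/3%) are chosen so each
experiment completes in seconds to ~1 minute on one CPU while leaving the
acceptance margins dominated by systematic, not sampling, error.

## Numerical and design choices

- **Self-match exclusion**: a query's own source occurrence (5' window of
  its source read) never counts; without it every count is ≥ 1 and
  low-effort coverage is biased upward. If the query copy was modified
  (error injection) its source window no longer matches and nothing is
  subtracted — the natural behavior.
- **Sampling without replacement** for queries; seeded, deterministic;
  no global random state anywhere.
- **Counting multiplicity**: multiple occurrences of a query k-mer within
  one read count per position (consistent with scanning every window).
- **Identity denominator** in the alignment kernel is overlap columns,
  not query length; the threshold comparison uses an epsilon-guarded
  integer bound so e.g. 94/100 < 0.95 ≤ 95/100 is exact.
- **Curve files** (`.npo`, TSV with `# key<TAB>value` headers) store
  efforts at full float precision; read(write(c)) is exact. Mandatory
  headers are validated by name.
- **Transform factor** multiplies match counts before rarefaction
  (default 1.0, identity); exposed for parity with the redundancy-to-
  coverage transformation option but with no further semantics.
- **Degenerate inputs**: empty FASTA records are skipped with a warning;
  IUPAC degeneracy codes map to N; windows containing N neither form
  queries nor match; all-zero curves and < 3 usable points raise fit
  errors rather than returning garbage.

## Known limitations

Single reads only (pairs must be reduced to one mate or merged upstream —
redundancy assumes independent draws); no quality trimming or adapter
clipping; per-base error above ~5% breaks the error-correction
assumption; no confidence intervals on Nd; the alignment kernel is
quadratic and intended for moderate datasets or cross-checks; simulated
communities understate kernel disagreement relative to real metagenomes.
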