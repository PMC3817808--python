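# Methods

## Model and scope

The package infers a gene regulatory network from discretized expression data
under the probabilistic gene network (PGN) view: gene states evolve as a
first-order Markov chain whose per-gene transition function is homogeneous in
time, *almost deterministic* (one preferential next state per predictor
configuration, left with probability ε) and conditionally independent across
genes. Inference is exhaustive feature selection with the predictor-subset
size fixed at 2: biological networks average 2–3 regulators per gene, and
with the dozens of samples typical of expression time courses, plug-in
entropy estimates over 3-predictor configuration spaces (8–27 cells already
at pairs) would be statistically hollow. Searches over larger subsets are
deliberately out of scope; the pair restriction is a guardrail, not a limit
of the architecture.

## Criterion

Scores are mean conditional entropies in bits computed from dense
`|A| × |A|²` count tables (A the alphabet). Estimates are maximum-likelihood
(no pseudo-counts, no penalty for configurations observed once); an additive
`pseudocount` option exists but defaults off, keeping the scoring exactly the
stated weighted-average formula. Conventions `0·log 0 = 0` and
"unobserved configuration contributes 0" fall out of the weighted sum.

Numerically, MCE is evaluated as
`Σ_x [ n_x log₂ n_x − Σ_y c_{y,x} log₂ c_{y,x} ] / N` with the subtraction
done **per configuration**, so a configuration that determines the target
cancels to exactly 0.0 rather than to rounding residue; perfectly predicted
targets therefore score an exact zero, which the tie logic relies on. One
vectorized kernel serves the scalar API, the tiled search and the brute-force
reference, so equal count tables always produce bit-identical doubles and
"exact tie" is well defined. The log base (2) only rescales scores and can
never reorder pairs.

## Search and scheduling

The tiled schedule partitions targets into k contiguous segments
(`targets_per_block` each) and predictors into 2k contiguous segments; each
block walks tile pairs (j₁, j₂), j₂ ≥ j₁, taking the full cross product off
the diagonal and the strict upper triangle on it. This enumerates each
unordered pair exactly once per target, which an evaluation counter verifies:
C(n_real, 2) pairs per target minus exclusions. Duplicated predictors (p, p)
are excluded — a repeated gene adds no configuration — and self-loops
(target as its own predictor) are excluded by default with an opt-in flag for
temporal data, where autoregulation is meaningful.

Per-target state is one running minimum plus its tie list; *all* pairs
attaining the minimum are reported, in lexicographic order, because "the
best pair" is frequently non-unique on discrete data and silently dropping
ties would make output depend on enumeration order. Tie comparison uses
exact float equality (sound because of the shared kernel); a `tie_tol`
widens the tie set for cross-platform comparisons and defaults to 0.

Workers: the m supersegments are a data-partitioning contract, not a
concurrency mechanism. They execute serially by default — determinism and
debuggability first — and `parallel=True` backs them with a process pool
over shared read-only input. Output is bit-identical either way and for any
(m, `targets_per_block`); the acceptance suite checks byte-identity of the
written files. Gene counts that do not divide evenly are padded with
constant neutral-state dummy genes, which never enter scoring or outputs.

With `targets_per_block` odd the classical equal predictor segments of size
n/2k do not exist; the predictor set is instead split into 2k contiguous
near-equal ranges (sizes differing by at most one). The equal case
reproduces the classical layout exactly.

## Cost model

Transfer counts are abstract segment/gene loads, hardware-free: per block
2k² + 3k predictor-segment loads (the sum 2 + 3 + … + (2k+1)) plus one
target-segment load; in total n·(k² + 3k/2 + 1/2) gene loads, a (n/k)²
saving over an unsegmented O(n³) scheme. Both printed forms of the total are
implemented and tested as an algebraic identity, and the per-block counts are
asserted against the scheduler's instrumented counters. The two conventions
(with/without the target-segment load) are both exposed: `transfers_per_block`
excludes it; the total includes it as the `+1`. The coalescing width (32) is
carried as metadata only — no count depends on it, and modeling bandwidth or
occupancy is a non-goal.

## Quantization

Continuous matrices are discretized per gene by z-score (population standard
deviation): ternary with threshold τ on the standardized scale, binary split
at z = 0. The default τ = 0.4307 (Φ(τ) = 2/3) gives equal-mass tertiles
under normality — equal-frequency states maximize the stability of plug-in
entropy estimates; the binary split at the mean is the simplest symmetric
rule. Zero-variance genes map to the neutral state and are flagged rather
than dropped. Missing values are rejected, not imputed: imputation policy
belongs upstream of an information-theoretic criterion. Quantized output is
invariant to any affine rescaling of a gene's raw values.

## Synthetic data

`pgn` draws Erdős–Rényi-style topologies with fixed in-degree 2 (a Poisson
in-degree variant sits behind a flag; its targets with in-degree ≠ 2 are then
only partially recoverable by a pair search, which is the realistic outcome,
not an error). Each target's predictors are drawn uniformly from the *other*
genes: a self-predictor would be unrecoverable under the search's default
self-loop exclusion, making noiseless recovery impossible by construction
rather than informative. Transition tables are uniform random over the
alphabet per configuration — the simplest distribution satisfying the PGN
properties. Noise is an independent per-gene ε-mixture: preferential state
with probability 1 − ε, otherwise uniform over the remaining states, so the
observed deviation frequency equals ε. Trajectories start from a uniform
random state; multiple trajectories are concatenated with boundaries
recorded, and lag alignment never pairs samples across a boundary.

What the simulator does **not** emulate: measurement noise on continuous
intensities, quantization artifacts, scale-free topology, hidden confounders,
non-stationary dynamics. Passing recovery tests therefore demonstrates the
search and criterion are correct and identifiable in-model; they do not
certify performance on real expression data.

## Default study conditions

Validation runs use ternary 32-gene networks, in-degree 2, ε = 0.05, 200
time steps (noiseless runs: ε = 0, 500 steps), 10 independent seeds — a
desk-scale stand-in for benchmark networks of 1024–8192 genes with 30
samples, sized so the whole suite runs in seconds while leaving the
recovery question statistically meaningful (320 targets pooled). The
temporal lag defaults to 1 on temporal matrices (the Markov pairing) and 0
otherwise. The CLI defaults to `targets_per_block = 128`, the block size at
which the schedule's redundant-load count is lowest among the classical
settings (32/64/128), clamped to the gene count for small inputs.

## Numerical and degenerate-input choices

* Entropies are float64 throughout; counts are exact integers from `bincount`.
* A constant target scores 0 with every pair — all pairs tie, and the full
  tie set is reported rather than an arbitrary representative.
* Empty predictor segments (possible after heavy padding or `targets_per_block
  = 1` with small n) contribute no pairs but still count as segment loads,
  keeping the instrumented counters equal to the closed form.
* `brute_force_oracle` refuses n > 512: it exists to check correctness, and
  an unguarded O(n³) reference invites misuse as a production path.

## Known limitations

* Pair-only search: targets with true in-degree > 2 are found only partially.
* Plug-in entropy is biased low for sparsely observed configurations; with
  very few samples the minimal-MCE pair can overfit. The pseudocount option
  mitigates but departs from the stated criterion.
* The cost model counts abstract loads; it predicts relative, not absolute,
  memory traffic.
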