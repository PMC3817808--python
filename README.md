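# mcenet

Exhaustive predictor-pair inference of gene regulatory networks by **mean
conditional entropy (MCE)**, with the blocked/tiled execution schedule of a
massively parallel all-pairs search, its analytic transfer-cost model, and a
probabilistic gene network simulator for end-to-end validation.

## The problem

Given a discretized gene-expression matrix — *s* samples × *n* genes over a
binary `{0, 1}` or ternary `{-1, 0, +1}` alphabet — network inference asks,
for every *target* gene *Y*, which *predictor* genes carry the most
information about it. Some targets are *intrinsically multivariate*: a pair
of genes explains them jointly while neither does alone (XOR-like logic),
which defeats greedy feature selection. The only way to guarantee the optimal
pair is to score **all** C(n, 2) candidate pairs per target — an O(n³)
search this package makes practical and, above all, *exactly reproducible
under any partitioning of the work*.

## The criterion

For a target *Y* and a predictor pair *X* = (X₁, X₂), with plug-in
probabilities from the joint count table over the aligned samples:

    H(Y)       = − Σ_y P(Y=y) log₂ P(Y=y)
    H(Y|X=x)   = − Σ_y P(Y=y|X=x) log₂ P(Y=y|X=x)
    H(Y|X)     =   Σ_x P(X=x) · H(Y|X=x)          (the MCE)

Lower is better; `H(Y|X) = 0` means the pair determines the target exactly in
the data. For temporal data the samples are lag-aligned: predictors at time
*t*, target at *t+1* (first-order Markov dynamics).

## The execution model

Targets are split into *k* contiguous segments of `targets_per_block` genes
(one per execution block) and predictors into 2*k* segments. Each block
enumerates tile pairs (j₁, j₂) with j₂ ≥ j₁, scoring every pair drawn from
P_j₁ × P_j₂ (strict upper triangle on the diagonal tile), so each unordered
pair is scored exactly once per target. For *m* workers the blocks are
grouped into *m* supersegments; every worker sees the whole predictor matrix
and only its own targets. The closed-form cost of the schedule — 2k² + 3k
predictor-segment loads per block, n·(k² + 3k/2 + 1/2) total gene loads,
a (n/k)² saving over the unsegmented scheme — is implemented and checked
against instrumented counters. Results are **bit-identical** for every choice
of `targets_per_block` and `m`.

## Worked example

`python examples/01_infer_from_simulated_network.py` simulates a 32-gene
ternary network (2 regulators per gene, 5% transition noise, 200 time
steps), infers it back and scores the recovery:

```
simulated 200 x 32 ternary matrix
scored 14880 predictor pairs (k=4 blocks, m=2 workers)
32 targets: exact 96.9%, partial 3.1%, miss 0.0% (mean tie-set size 1.00)
hardest target: g31 with minimal MCE 0.414 bits
```

14880 = 32 targets × C(31, 2) candidate pairs (self-loops excluded). "exact"
means the generating regulator pair is in the minimal-MCE tie set; the one
"partial" target shares a regulator with its best-scoring pair. The same runs
are available from the shell:

```
mcenet simulate -n 32 -s 200 --levels 3 --epsilon 0.05 --seed 7 \
       -o matrix.tsv --ground-truth gt
mcenet infer -i matrix.tsv --levels 3 --lag 1 -o network.tsv
mcenet validate --network network.tsv --ground-truth gt.pairs.tsv
mcenet costmodel -n 4096 --targets-per-block 128
```

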