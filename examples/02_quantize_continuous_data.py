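"""Quantize continuous expression values into ternary states by z-score.

Each gene is standardized over the samples; values below -tau map to -1
(underexpressed), above +tau to +1 (overexpressed), the rest to 0 (normal).
The default tau = 0.4307 puts one third of a standard-normal gene's samples
in each state.
"""

import numpy as np

from mcenet import DEFAULT_TAU, QuantizationConfig, quantize_zscore

rng = np.random.default_rng(1)
raw = rng.standard_normal((60, 5)) * rng.uniform(0.5, 4.0, size=5) + rng.normal(0, 10, size=5)

matrix = quantize_zscore(raw, QuantizationConfig(levels=3, tau=DEFAULT_TAU))
print(f"quantized {matrix.n_samples} x {matrix.n_genes} matrix, alphabet {matrix.alphabet}")
for state in matrix.alphabet:
    print(f"  state {state:+d}: frequency {(matrix.values == state).mean():.3f}")
# frequencies near 1/3 each: the per-gene scale and offset are divided out,
# so only the shape of each gene's distribution matters.
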