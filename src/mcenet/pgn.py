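"""Probabilistic gene network (PGN) simulator and recovery scoring.

A PGN is a discrete first-order Markov model of a gene network: each gene's
state at time ``t+1`` depends only on its predictors' states at time ``t``,
through a transition function that is homogeneous (the same at every step),
almost deterministic (each predictor configuration has one *preferential*
next state, taken with probability ``1 - epsilon``) and conditionally
independent across genes.

The generator emulates the benchmark regime used to validate exhaustive pair
search: Erdős–Rényi-style random topologies with a fixed in-degree of 2
(biological networks average 2–3 regulators per gene), binary or ternary
states, and short time courses (30 samples is the canonical microarray-scale
setting).  An optional Poisson in-degree variant is available; targets with
in-degree != 2 are then only partially recoverable by a pair search, which is
the realistic situation, not a defect.

Ground truth (topology + transition tables) is retained so that inference
results can be scored for exact/partial predictor recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io import BINARY, TERNARY, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PGNParams:
    """Simulation settings.

    ``epsilon`` is the probability that a gene deviates from its preferential
    next state (spread uniformly over the remaining states); ``s`` the number
    of time points per trajectory; ``n_trajectories`` independent time
    courses are concatenated (lagged alignment never crosses the boundaries).
    """

    n: int
    in_degree: int = 2
    alphabet: tuple[int, ...] = BINARY
    epsilon: float = 0.05
    s: int = 30
    n_trajectories: int = 1
    seed: int | None = None
    poisson_degree: bool = False

    def __post_init__(self) -> None:
        if not 2 <= self.n:
            raise ConfigurationError("need at least 2 genes")
        if not 1 <= self.in_degree < self.n:
            raise ConfigurationError("in_degree must be in [1, n)")
        if not 0 <= self.epsilon < 1:
            raise ConfigurationError("epsilon must be in [0, 1)")
        if self.s < 2:
            raise ConfigurationError("need at least 2 samples per trajectory")
        if tuple(self.alphabet) not in (BINARY, TERNARY):
            raise ConfigurationError(f"unsupported alphabet {self.alphabet}")


@dataclass
class GroundTruthNetwork:
    """Simulated topology plus per-target transition tables.

    ``predictors[t]`` lists target ``t``'s regulator indices;
    ``transition[t]`` maps each predictor configuration (mixed-radix index
    over state codes, first predictor most significant) to the preferential
    next-state code.
    """

    predictors: list[tuple[int, ...]]
    transition: list[np.ndarray]
    params: PGNParams

    def __post_init__(self) -> None:
        a = len(self.params.alphabet)
        for t, (preds, table) in enumerate(zip(self.predictors, self.transition)):
            if len(set(preds)) != len(preds):
                raise ValidationError(f"target {t}: repeated predictor")
            if table.shape != (a ** len(preds),):
                raise ValidationError(f"target {t}: transition table size mismatch")

    def true_pair(self, t: int) -> tuple[int, ...]:
        return tuple(sorted(self.predictors[t]))


def generate_network(params: PGNParams) -> GroundTruthNetwork:
    """Draw a random topology and random transition tables.

    Each target receives ``in_degree`` distinct predictors chosen uniformly
    from the *other* genes (a self-predictor would be indistinguishable from
    trivial autocorrelation and unrecoverable under the search's default
    self-loop exclusion).  Each configuration's preferential state is uniform
    over the alphabet.  Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    a = len(params.alphabet)
    predictors: list[tuple[int, ...]] = []
    transition: list[np.ndarray] = []
    for t in range(params.n):
        candidates = np.delete(np.arange(params.n), t)
        if params.poisson_degree:
            d = int(np.clip(rng.poisson(params.in_degree), 1, params.n - 1))
        else:
            d = params.in_degree
        preds = tuple(int(p) for p in rng.choice(candidates, size=d, replace=False))
        predictors.append(preds)
        transition.append(rng.integers(0, a, size=a ** d, dtype=np.int64))
    return GroundTruthNetwork(predictors=predictors, transition=transition, params=params)


def _step(net: GroundTruthNetwork, state: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One synchronous update of all genes (state holds codes 0..a-1)."""
    a = len(net.params.alphabet)
    nxt = np.empty_like(state)
    for t, preds in enumerate(net.predictors):
        cfg = 0
        for p in preds:
            cfg = cfg * a + state[p]
        nxt[t] = net.transition[t][cfg]
    eps = net.params.epsilon
    if eps > 0:
        noisy = rng.random(state.size) < eps
        if noisy.any():
            offsets = rng.integers(1, a, size=int(noisy.sum()))
            nxt[noisy] = (nxt[noisy] + offsets) % a
    return nxt


def simulate_trajectory(
    net: GroundTruthNetwork,
    s: int | None = None,
    seed: int | None = None,
    n_trajectories: int | None = None,
) -> ExpressionMatrix:
    """Sample temporal expression data from the network.

    Row 0 of each trajectory is uniform over states; each subsequent row
    applies the transition tables, deviating from the preferential state with
    probability ``epsilon`` (uniform over the other states).  Defaults for
    ``s``/``seed``/``n_trajectories`` come from the network's params.
    """
    p = net.params
    s = p.s if s is None else s
    n_traj = p.n_trajectories if n_trajectories is None else n_trajectories
    if s < 2:
        raise ConfigurationError("need at least 2 time points")
    rng = np.random.default_rng(p.seed if seed is None else seed)
    a = len(p.alphabet)
    rows = []
    starts = []
    row_count = 0
    for _ in range(n_traj):
        starts.append(row_count)
        state = rng.integers(0, a, size=p.n, dtype=np.int64)
        rows.append(state)
        row_count += 1
        for _ in range(s - 1):
            state = _step(net, state, rng)
            rows.append(state)
            row_count += 1
    codes = np.vstack(rows)
    states = np.asarray(p.alphabet, dtype=np.int64)[codes]
    return ExpressionMatrix(
        values=states,
        gene_names=[f"g{j}" for j in range(p.n)],
        alphabet=tuple(p.alphabet),
        is_temporal=True,
        trajectory_starts=tuple(starts),
    )


@dataclass
class RecoveryReport:
    """How well an inference run recovered the generating topology.

    Per target: ``exact`` — the true predictor pair is in the minimal-MCE tie
    set; ``partial`` — at least one true predictor appears in some tied pair;
    ``miss`` — neither.  Targets whose true in-degree differs from 2 can
    never be exact by definition and are counted separately.
    """

    status: list[str]
    n_ties: list[int]
    exact_fraction: float
    partial_fraction: float
    miss_fraction: float
    n_targets: int
    n_nonpair_targets: int = 0
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"{self.n_targets} targets: exact {self.exact_fraction:.1%}, "
            f"partial {self.partial_fraction:.1%}, miss {self.miss_fraction:.1%} "
            f"(mean tie-set size {np.mean(self.n_ties):.2f})"
        )


def recovery_report(net: GroundTruthNetwork, result) -> RecoveryReport:
    """Score an :class:`~mcenet.search.InferenceResult` against the truth.

    The result must come from data simulated by ``net`` with lag-1 alignment,
    over the same gene set.
    """
    real_names = [f"g{j}" for j in range(net.params.n)]
    result_names = [
        n for n, d in zip(result.gene_names, result.dummy_mask) if not d
    ]
    if result_names != real_names:
        raise ConfigurationError("result gene set does not match the network")
    by_name = result.pairs_by_name()
    status: list[str] = []
    n_ties: list[int] = []
    nonpair = 0
    for t in range(net.params.n):
        truth = net.true_pair(t)
        ties = [
            tuple(sorted((int(p1[1:]), int(p2[1:])))) for p1, p2 in by_name[f"g{t}"]
        ]
        n_ties.append(len(ties))
        if len(truth) != 2:
            nonpair += 1
        true_set = set(truth)
        if len(truth) == 2 and truth in ties:
            status.append("exact")
        elif any(true_set & set(pair) for pair in ties):
            status.append("partial")
        else:
            status.append("miss")
    n = len(status)
    return RecoveryReport(
        status=status,
        n_ties=n_ties,
        exact_fraction=status.count("exact") / n,
        partial_fraction=status.count("partial") / n,
        miss_fraction=status.count("miss") / n,
        n_targets=n,
        n_nonpair_targets=nonpair,
    )


# ---------------------------------------------------------------------------
# ground-truth serialization (plain text)
# ---------------------------------------------------------------------------

def write_ground_truth(net: GroundTruthNetwork, pairs_path, tables_path) -> None:
    """Write the topology as TSV and the transition tables as key-value text.

    Pairs TSV columns: target and one column per predictor.  Tables file
    lines: ``target=<name> predictors=<p,p,...> table=<code,code,...>``.
    """
    with open(pairs_path, "w", encoding="utf-8") as fh:
        fh.write("target\t" + "\t".join(
            f"predictor{i+1}" for i in range(max(len(p) for p in net.predictors))
        ) + "\n")
        for t, preds in enumerate(net.predictors):
            fh.write(f"g{t}\t" + "\t".join(f"g{p}" for p in preds) + "\n")
    with open(tables_path, "w", encoding="utf-8") as fh:
        fh.write(f"# alphabet={','.join(str(a) for a in net.params.alphabet)}\n")
        fh.write(f"# epsilon={net.params.epsilon}\n")
        for t, (preds, table) in enumerate(zip(net.predictors, net.transition)):
            preds_s = ",".join(f"g{p}" for p in preds)
            table_s = ",".join(str(int(v)) for v in table)
            fh.write(f"target=g{t} predictors={preds_s} table={table_s}\n")


def read_ground_truth_pairs(pairs_path) -> dict[str, tuple[str, ...]]:
    """Read the pairs TSV back into ``{target: (predictor names...)}``."""
    out: dict[str, tuple[str, ...]] = {}
    with open(pairs_path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("target"):
            raise ValidationError(f"{pairs_path}: not a ground-truth pairs file")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = tuple(p for p in parts[1:] if p)
    return out
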