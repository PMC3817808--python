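"""Discrete expression matrices: loading, validation, quantization, padding, lagging.

The central container is :class:`ExpressionMatrix`: an ``s x n`` integer matrix
(rows = samples, columns = genes) over a small ordered alphabet, either binary
``(0, 1)`` or ternary ``(-1, 0, +1)`` ("underexpressed / normal /
overexpressed").  Temporal matrices carry trajectory boundaries so that
first-order (lag-1) predictor/target alignment never pairs samples across
independent time courses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    InsufficientSamplesError,
    ValidationError,
)

logger = logging.getLogger(__name__)

BINARY = (0, 1)
TERNARY = (-1, 0, 1)

#: Constant value used for padding ("dummy") genes in both alphabets.
NEUTRAL_STATE = 0

#: Default ternary threshold on the z-score scale.  Phi(0.4307) = 2/3, so a
#: standard-normal gene falls in each of the three states with probability 1/3
#: (equal-frequency states keep the plug-in entropy estimates stable).
DEFAULT_TAU = 0.4307

DUMMY_PREFIX = "__dummy"


@dataclass
class ExpressionMatrix:
    """A validated s x n discrete expression matrix.

    Parameters
    ----------
    values
        Integer matrix, rows are samples (time points if ``is_temporal``),
        columns are genes.  Every entry must belong to ``alphabet``.
    gene_names
        Unique column labels, one per gene.
    alphabet
        Ordered discrete state set, ``BINARY`` or ``TERNARY`` (any strictly
        increasing tuple of small ints is accepted).
    is_temporal
        Rows are consecutive time points; required for lagged alignment.
    dummy_mask
        Per-gene flag marking constant padding genes (excluded from results).
    trajectory_starts
        Row indices at which independent time courses begin (always includes 0).
    constant_mask
        Set by :func:`quantize_zscore` for genes with zero variance.
    """

    values: np.ndarray
    gene_names: list[str]
    alphabet: tuple[int, ...] = BINARY
    is_temporal: bool = False
    dummy_mask: np.ndarray | None = None
    trajectory_starts: tuple[int, ...] = (0,)
    constant_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D samples x genes matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.issubdtype(self.values.dtype, np.floating) and np.isnan(self.values).any():
                raise ValidationError("missing values are not supported")
            rounded = np.rint(self.values)
            if not np.array_equal(rounded, self.values):
                raise ValidationError("expression values must be integers")
            self.values = rounded.astype(np.int64)
        self.alphabet = tuple(int(a) for a in self.alphabet)
        self.gene_names = [str(g) for g in self.gene_names]
        s, n = self.values.shape
        if len(self.gene_names) != n:
            raise ValidationError(
                f"{len(self.gene_names)} gene names for {n} columns"
            )
        if len(set(self.gene_names)) != n:
            dupes = sorted({g for g in self.gene_names if self.gene_names.count(g) > 1})
            raise ValidationError(f"duplicate gene names: {dupes[:5]}")
        bad = ~np.isin(self.values, self.alphabet)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"value {self.values[i, j]} at sample {i}, gene {self.gene_names[j]!r} "
                f"is outside alphabet {self.alphabet}"
            )
        if self.dummy_mask is None:
            self.dummy_mask = np.zeros(n, dtype=bool)
        else:
            self.dummy_mask = np.asarray(self.dummy_mask, dtype=bool)
            if self.dummy_mask.shape != (n,):
                raise ValidationError("dummy_mask length must match gene count")
            for j in np.flatnonzero(self.dummy_mask):
                col = self.values[:, j]
                if not np.all(col == NEUTRAL_STATE):
                    raise ValidationError(
                        f"dummy gene {self.gene_names[j]!r} is not constant {NEUTRAL_STATE}"
                    )
        starts = tuple(int(t) for t in self.trajectory_starts)
        increasing = list(starts) == sorted(set(starts))
        if not starts or starts[0] != 0 or not increasing or (s > 0 and starts[-1] >= s):
            if not (starts == (0,) and s == 0):
                raise ValidationError(f"invalid trajectory_starts {starts} for s={s}")
        self.trajectory_starts = starts

    # -- basic introspection ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_real_genes(self) -> int:
        return int((~self.dummy_mask).sum())

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def encoded(self) -> np.ndarray:
        """Values mapped to contiguous codes ``0 .. len(alphabet)-1``."""
        lut = {state: i for i, state in enumerate(self.alphabet)}
        out = np.empty(self.values.shape, dtype=np.int64)
        for state, code in lut.items():
            out[self.values == state] = code
        return out

    def trajectory_bounds(self) -> list[tuple[int, int]]:
        """Half-open row ranges of the independent time courses."""
        starts = list(self.trajectory_starts) + [self.n_samples]
        return [(starts[i], starts[i + 1]) for i in range(len(starts) - 1)]


@dataclass(frozen=True)
class QuantizationConfig:
    """Z-score quantization settings (``levels`` 2 or 3, ``tau`` > 0)."""

    levels: int = 3
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if self.levels not in (2, 3):
            raise ConfigurationError("quantization levels must be 2 or 3")
        if self.levels == 3 and not self.tau > 0:
            raise ConfigurationError("ternary threshold tau must be positive")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise FormatError(f"{path}: empty file")


def read_matrix(
    path,
    alphabet: tuple[int, ...] = BINARY,
    *,
    is_temporal: bool = False,
    trajectory_starts: tuple[int, ...] = (0,),
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix (header row of gene names, one row per
    sample; ``#`` lines are ignored).  Set ``transpose`` for genes x samples
    files.  Row order is preserved — it is the temporal order."""
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", header=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if transpose:
        df = df.set_index(df.columns[0]).T
        gene_names = list(df.columns)
        values = df.to_numpy()
    else:
        gene_names = list(df.columns)
        values = df.to_numpy()
    if pd.DataFrame(values).isna().any().any():
        raise ValidationError(f"{path}: missing values are not supported")
    try:
        return ExpressionMatrix(
            values=values,
            gene_names=gene_names,
            alphabet=alphabet,
            is_temporal=is_temporal,
            trajectory_starts=trajectory_starts,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_matrix(matrix: ExpressionMatrix, path, *, header_lines: list[str] | None = None) -> None:
    """Write a matrix as TSV (gene-name header, one row per sample).

    ``header_lines`` are emitted as leading ``#`` comments; :func:`read_matrix`
    skips them, so write → read round-trips the values and names exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(matrix.gene_names) + "\n")
        np.savetxt(fh, matrix.values, fmt="%d", delimiter="\t")


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize_zscore(
    raw,
    config: QuantizationConfig | None = None,
    *,
    gene_names: list[str] | None = None,
    is_temporal: bool = False,
    trajectory_starts: tuple[int, ...] = (0,),
) -> ExpressionMatrix:
    """Discretize a continuous s x n matrix by per-gene z-score thresholding.

    Each gene column is standardized to zero mean and unit variance over the
    samples (population standard deviation).  Ternary: ``z < -tau -> -1``,
    ``|z| <= tau -> 0``, ``z > tau -> +1``.  Binary: ``z <= 0 -> 0``,
    ``z > 0 -> 1``.  Zero-variance genes map to the neutral state and are
    flagged in ``constant_mask``.
    """
    config = config or QuantizationConfig()
    if isinstance(raw, pd.DataFrame):
        gene_names = gene_names or [str(c) for c in raw.columns]
        raw = raw.to_numpy(dtype=float)
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValidationError("raw matrix must be 2-D samples x genes")
    s, n = raw.shape
    if s < 2:
        raise InsufficientSamplesError(f"z-scoring needs at least 2 samples, got {s}")
    if np.isnan(raw).any():
        raise ValidationError("missing values are not supported")
    if gene_names is None:
        gene_names = [f"g{j}" for j in range(n)]

    mean = raw.mean(axis=0)
    std = raw.std(axis=0)  # population (ddof=0); affine-invariant either way
    constant = std == 0
    safe_std = np.where(constant, 1.0, std)
    z = (raw - mean) / safe_std

    if config.levels == 2:
        values = (z > 0).astype(np.int64)
        alphabet = BINARY
    else:
        values = np.zeros_like(z, dtype=np.int64)
        values[z < -config.tau] = -1
        values[z > config.tau] = 1
        alphabet = TERNARY
    values[:, constant] = NEUTRAL_STATE
    if constant.any():
        names = [gene_names[j] for j in np.flatnonzero(constant)]
        logger.warning("constant genes mapped to neutral state: %s", names[:10])
    return ExpressionMatrix(
        values=values,
        gene_names=list(gene_names),
        alphabet=alphabet,
        is_temporal=is_temporal,
        trajectory_starts=trajectory_starts,
        constant_mask=constant,
    )


# ---------------------------------------------------------------------------
# lagging and padding
# ---------------------------------------------------------------------------

def lag_align(matrix: ExpressionMatrix, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Return aligned ``(predictor_rows, target_rows)`` value views.

    Under the first-order Markov model a target's value at time ``t`` is
    explained by its predictors' values at time ``t - lag``.  With ``lag=0``
    both views are the full matrix.  Sample pairs that would straddle a
    trajectory boundary are dropped.
    """
    if lag < 0:
        raise ConfigurationError("lag must be non-negative")
    if lag == 0:
        return matrix.values, matrix.values
    if not matrix.is_temporal:
        raise ConfigurationError("lagged alignment requires a temporal matrix")
    pred_idx: list[np.ndarray] = []
    targ_idx: list[np.ndarray] = []
    for start, end in matrix.trajectory_bounds():
        if end - start > lag:
            pred_idx.append(np.arange(start, end - lag))
            targ_idx.append(np.arange(start + lag, end))
    if not pred_idx:
        raise InsufficientSamplesError(
            f"lag {lag} leaves no aligned sample pairs (s={matrix.n_samples})"
        )
    p = np.concatenate(pred_idx)
    t = np.concatenate(targ_idx)
    return matrix.values[p], matrix.values[t]


def pad_dummy_genes(matrix: ExpressionMatrix, multiple: int) -> ExpressionMatrix:
    """Append constant neutral-state genes until ``n`` divides ``multiple``.

    Padding lets gene counts divide evenly into segments; dummy genes are
    flagged and never participate in scoring or appear in outputs.
    """
    if multiple < 1:
        raise ConfigurationError("multiple must be >= 1")
    n = matrix.n_genes
    n_target = -(-n // multiple) * multiple
    if n_target == n:
        return matrix
    extra = n_target - n
    pad = np.full((matrix.n_samples, extra), NEUTRAL_STATE, dtype=matrix.values.dtype)
    existing = set(matrix.gene_names)
    names, j = [], 0
    while len(names) < extra:
        cand = f"{DUMMY_PREFIX}_{j}"
        if cand not in existing:
            names.append(cand)
        j += 1
    mask = np.concatenate([matrix.dummy_mask, np.ones(extra, dtype=bool)])
    const = None
    if matrix.constant_mask is not None:
        const = np.concatenate([matrix.constant_mask, np.zeros(extra, dtype=bool)])
    return ExpressionMatrix(
        values=np.hstack([matrix.values, pad]),
        gene_names=matrix.gene_names + names,
        alphabet=matrix.alphabet,
        is_temporal=matrix.is_temporal,
        dummy_mask=mask,
        trajectory_starts=matrix.trajectory_starts,
        constant_mask=const,
    )


# ---------------------------------------------------------------------------
# network output
# ---------------------------------------------------------------------------

def write_network(result, path, format: str = "edge-list") -> None:
    """Write an inference result as an edge-list TSV or a SIF file.

    Edge list columns: ``target, predictor1, predictor2, mce, tie_rank`` (all
    minimal-MCE ties share rank 1).  SIF emits one ``regulates`` edge per
    (predictor, target).  Dummy genes are never written.
    """
    if format not in ("edge-list", "sif"):
        raise ConfigurationError(f"unknown network format {format!r}")
    rows = result.to_rows()
    if not rows:
        raise ValidationError("refusing to write an empty inference result")
    is_dummy = {name: bool(d) for name, d in zip(result.gene_names, result.dummy_mask)}
    try:
        fh = open(path, "w", encoding="utf-8")
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
    with fh:
        if format == "edge-list":
            for key, val in sorted(result.file_provenance().items()):
                fh.write(f"# {key}: {val}\n")
            fh.write("target\tpredictor1\tpredictor2\tmce\ttie_rank\n")
        seen_sif = set()
        for target, p1, p2, mce in rows:
            if is_dummy.get(p1) or is_dummy.get(p2) or is_dummy.get(target):
                logger.warning("dropping dummy-gene edge (%s, %s) -> %s", p1, p2, target)
                continue
            if format == "edge-list":
                fh.write(f"{target}\t{p1}\t{p2}\t{mce:.12g}\t1\n")
            else:
                for p in (p1, p2):
                    if (p, target) not in seen_sif:
                        seen_sif.add((p, target))
                        fh.write(f"{p}\tregulates\t{target}\n")


def read_network(path) -> dict[str, list[tuple[str, str, float]]]:
    """Read an edge-list TSV back into ``{target: [(p1, p2, mce), ...]}``."""
    out: dict[str, list[tuple[str, str, float]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header_seen = False
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if not header_seen:
                header_seen = True
                continue
            target, p1, p2, mce, _rank = line.rstrip("\n").split("\t")
            out.setdefault(target, []).append((p1, p2, float(mce)))
    if not header_seen:
        raise FormatError(f"{path}: empty network file")
    return out
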