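"""Core aTMM normalization mathematics.

Everything here is deterministic and pure: given a count matrix, the module
computes per-pair M/A statistics, selects trim fractions by minimizing a
discrete (Jaeckel) estimate of the trimmed mean's asymptotic variance, builds
an n x n log2 scale-factor matrix using every sample as a reference, and
aggregates per-sample factors by geometric mean across references.

Conventions
-----------
* ``log2_factor_matrix[r][k]`` is the log2 normalization factor of sample
  ``k`` computed against reference ``r``; the diagonal is exactly zero.
* Trim counts use the floor convention ``t = floor(alpha * n)``; values of
  ``alpha * n`` within 1e-9 of an integer are snapped to it so that grid
  points ``alpha = t / n`` survive floating-point round-trips.
* Genes with a zero count in either member of a pair are dropped from that
  pair only; no pseudocounts are added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CountMatrix",
    "PairwiseMA",
    "TrimConfig",
    "NormalizationResult",
    "DegenerateSampleError",
    "DegeneratePairError",
    "library_sizes",
    "pairwise_ma",
    "alpha_trimmed_mean",
    "jaeckel_variance",
    "optimal_alpha",
    "dual_trim",
    "pairwise_log_factor",
    "factor_matrix",
    "aggregate_factors",
    "normalize",
    "classic_tmm",
]


class DegenerateSampleError(ValueError):
    """A sample is unusable for normalization (e.g. zero library size)."""


class DegeneratePairError(ValueError):
    """A (sample, reference) pair has too few usable genes.

    Raised by the pairwise primitives; :func:`factor_matrix` catches it and
    records a warning instead of failing.
    """


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """A genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        2-D array of shape (n_genes, n_samples); entries must be
        non-negative and integral (integer dtype, or floats with integral
        values, which are cast).
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    """

    counts: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __init__(self, counts, gene_ids, sample_ids):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.size == 0:
            raise ValueError("counts matrix is empty")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.issubdtype(counts.dtype, np.floating):
                raise ValueError(f"counts must be numeric, got dtype {counts.dtype}")
            if not np.all(np.isfinite(counts)):
                raise ValueError("counts contain non-finite values")
            if np.any(counts != np.round(counts)):
                g, s = np.argwhere(counts != np.round(counts))[0]
                raise ValueError(
                    f"non-integer count {counts[g, s]!r} at gene row {g}, sample column {s}"
                )
        if np.any(counts < 0):
            g, s = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count {counts[g, s]!r} at gene row {g}, sample column {s}"
            )
        counts = counts.astype(np.int64)
        gene_ids = tuple(str(g) for g in gene_ids)
        sample_ids = tuple(str(s) for s in sample_ids)
        if len(gene_ids) != counts.shape[0]:
            raise ValueError(
                f"{len(gene_ids)} gene ids for {counts.shape[0]} rows"
            )
        if len(sample_ids) != counts.shape[1]:
            raise ValueError(
                f"{len(sample_ids)} sample ids for {counts.shape[1]} columns"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PairwiseMA:
    """Gene-wise M/A statistics for one (sample k, reference r) pair.

    Only genes with a positive count in *both* samples are retained;
    ``gene_index`` holds their row indices into the original matrix.
    ``var`` is the delta-method (binomial) variance of M,
    ``(N_k - Y_gk)/(N_k * Y_gk) + (N_r - Y_gr)/(N_r * Y_gr)``.
    """

    sample_index: int
    reference_index: int
    gene_index: np.ndarray
    M: np.ndarray
    A: np.ndarray
    var: np.ndarray

    @property
    def n_retained(self) -> int:
        return len(self.gene_index)


@dataclass(frozen=True)
class TrimConfig:
    """Configuration of the trimming / aggregation behaviour.

    ``delta`` bounds the adaptive trim-fraction search (alpha in [0, delta)).
    A fixed ``fixed_alpha_m`` / ``fixed_alpha_a`` disables the adaptive
    search for M and/or A and uses the given fraction for every pair;
    ``None`` requests the adaptive search. By default only the M trim is
    adaptive: the Jaeckel criterion optimizes the trimmed mean of M -- the
    statistic the factor is built from -- whereas the A trim is a plain
    expression pre-filter kept at the customary 5%.

    ``alpha_cap`` additionally caps the adaptive search so the untrimmed
    core keeps at least 20% of the values: the discrete variance estimate
    V_n(alpha) is only trustworthy when the core grows linearly with n, and
    without the cap the argmin degenerates to the near-total trims where
    V_n collapses to ~0 on a handful of (often tied) middle order
    statistics. Set ``alpha_cap=0.5`` to search the full [0, delta) range.
    """

    delta: float = 0.5
    fixed_alpha_m: float | None = None
    fixed_alpha_a: float | None = 0.05
    min_genes_after_trim: int = 10
    renormalize_factors: bool = True
    alpha_cap: float = 0.4

    def __post_init__(self):
        if not (0.0 < self.delta <= 0.5):
            raise ValueError(f"delta must be in (0, 0.5], got {self.delta}")
        if not (0.0 < self.alpha_cap <= 0.5):
            raise ValueError(f"alpha_cap must be in (0, 0.5], got {self.alpha_cap}")
        for name, a in (("fixed_alpha_m", self.fixed_alpha_m),
                        ("fixed_alpha_a", self.fixed_alpha_a)):
            if a is not None:
                if not (0.0 <= a < 0.5):
                    raise ValueError(f"{name} must be in [0, 0.5), got {a}")
                if a >= self.delta:
                    raise ValueError(f"{name}={a} must be < delta={self.delta}")
        if self.min_genes_after_trim < 1:
            raise ValueError("min_genes_after_trim must be positive")


@dataclass(frozen=True)
class NormalizationResult:
    """Output of :func:`normalize`.

    ``alpha_table`` maps ``(reference_index, sample_index)`` to the selected
    ``(alpha_m, alpha_a)``; ``warnings`` lists ``(r, k, reason)`` for pairs
    whose factor was set to zero because too few genes survived.
    """

    log2_factor_matrix: np.ndarray
    factors: np.ndarray
    effective_library_sizes: np.ndarray
    alpha_table: dict[tuple[int, int], tuple[float, float]]
    warnings: list[tuple[int, int, str]] = field(default_factory=list)
    sample_ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Trim-count helpers
# ---------------------------------------------------------------------------


def _trim_count(alpha: float, n: int) -> int:
    """floor(alpha * n), snapping near-integer products to the integer."""
    if not (0.0 <= alpha < 0.5):
        raise ValueError(f"alpha must be in [0, 0.5), got {alpha}")
    t = alpha * n
    nearest = round(t)
    if abs(t - nearest) < 1e-9:
        return int(nearest)
    return int(math.floor(t))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def library_sizes(counts: CountMatrix) -> np.ndarray:
    """Per-sample total read counts (column sums).

    Raises :class:`DegenerateSampleError` if any sample has total count 0.
    """
    sizes = counts.counts.sum(axis=0)
    if np.any(sizes == 0):
        bad = int(np.argmax(sizes == 0))
        raise DegenerateSampleError(
            f"sample {counts.sample_ids[bad]!r} has library size 0"
        )
    return sizes


def pairwise_ma(counts: CountMatrix, k: int, r: int) -> PairwiseMA:
    """M/A statistics of sample ``k`` against reference ``r``.

    M = log2(Y_gk/N_k) - log2(Y_gr/N_r);
    A = 0.5 * log2((Y_gk/N_k) * (Y_gr/N_r));
    var = (N_k - Y_gk)/(N_k*Y_gk) + (N_r - Y_gr)/(N_r*Y_gr).

    Genes with a zero count in either sample are excluded. Raises
    :class:`DegeneratePairError` if fewer than 2 genes survive.
    """
    if k == r:
        raise ValueError("sample and reference must differ")
    sizes = library_sizes(counts)
    y_k = counts.counts[:, k].astype(np.float64)
    y_r = counts.counts[:, r].astype(np.float64)
    n_k = float(sizes[k])
    n_r = float(sizes[r])
    keep = (y_k > 0) & (y_r > 0)
    gene_index = np.flatnonzero(keep)
    if len(gene_index) < 2:
        raise DegeneratePairError(
            f"pair (sample {k}, reference {r}): only {len(gene_index)} genes "
            "expressed in both samples"
        )
    y_k = y_k[keep]
    y_r = y_r[keep]
    p_k = y_k / n_k
    p_r = y_r / n_r
    m = np.log2(p_k) - np.log2(p_r)
    a = 0.5 * np.log2(p_k * p_r)
    var = (n_k - y_k) / (n_k * y_k) + (n_r - y_r) / (n_r * y_r)
    return PairwiseMA(sample_index=k, reference_index=r,
                      gene_index=gene_index, M=m, A=a, var=var)


def alpha_trimmed_mean(x: np.ndarray, alpha: float) -> float:
    """Mean of ``x`` after removing ``floor(alpha*n)`` values from each tail."""
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 1:
        raise ValueError("empty vector")
    t = _trim_count(alpha, n)
    if n - 2 * t < 1:
        raise ValueError(f"trimming alpha={alpha} removes all {n} values")
    xs = np.sort(x)
    return float(xs[t:n - t].mean())


def _jaeckel_sorted(xs: np.ndarray, alpha: float) -> float:
    """Jaeckel variance estimate on an already-sorted vector."""
    n = len(xs)
    t = _trim_count(alpha, n)
    if n - 2 * t < 1:
        raise ValueError(f"trimming alpha={alpha} removes all {n} values")
    core = xs[t:n - t]
    mu = core.mean()
    inner = float(np.sum((core - mu) ** 2)) / n
    tails = alpha * (xs[t] - mu) ** 2 + alpha * (xs[n - t - 1] - mu) ** 2
    return float((inner + tails) / (1.0 - 2.0 * alpha) ** 2)


def jaeckel_variance(x: np.ndarray, alpha: float) -> float:
    """Discrete estimate V_n(alpha) of the alpha-trimmed mean's asymptotic
    variance (Jaeckel's plug-in estimator).

    With order statistics x_(1) <= ... <= x_(n), trim count t = floor(alpha*n)
    and mu the (alpha-)trimmed mean:

        V_n(alpha) = (1 - 2*alpha)^-2 * [ (1/n) * sum_{i=t+1}^{n-t} (x_(i)-mu)^2
                     + alpha*(x_(t+1)-mu)^2 + alpha*(x_(n-t)-mu)^2 ]
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 1:
        raise ValueError("empty vector")
    return _jaeckel_sorted(np.sort(x), alpha)


def optimal_alpha(
    x: np.ndarray, delta: float = 0.5, alpha_cap: float = 0.4
) -> tuple[float, float]:
    """Trim fraction minimizing V_n(alpha) over the discrete grid.

    The grid is ``alpha = t/n`` for integer ``t`` with
    ``0 <= t/n < min(delta, alpha_cap, (n-1)/(2n))``. The last bound keeps
    at least one untrimmed value; ``alpha_cap`` (default 0.4, i.e. the core
    keeps at least 20% of the values) guards against the finite-sample
    degeneracy of V_n at near-total trims, where the estimate collapses to
    ~0 on a few middle order statistics (see :class:`TrimConfig`). Ties are
    broken toward the smallest alpha (least data discarded).

    Returns ``(alpha_opt, V_min)``.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 values, got {n}")
    bound = min(delta, alpha_cap, (n - 1) / (2 * n))
    # largest integer t with t/n strictly below bound
    t_max = int(math.ceil(n * bound - 1e-9)) - 1
    if t_max < 0:
        raise ValueError(f"empty alpha grid for n={n}, delta={delta}")
    xs = np.sort(x)
    best_t = 0
    best_v = _jaeckel_sorted(xs, 0.0)
    for t in range(1, t_max + 1):
        v = _jaeckel_sorted(xs, t / n)
        if v < best_v:
            best_v = v
            best_t = t
    return best_t / n, best_v


def dual_trim(stats: PairwiseMA, alpha_m: float, alpha_a: float) -> np.ndarray:
    """Positions (into the retained-gene arrays of ``stats``) surviving both
    the M-trim and the A-trim.

    Each trim removes ``floor(alpha * n')`` genes from each tail of the
    corresponding statistic's ranking; ties are resolved by a stable sort
    (value, then original position). The result is the sorted intersection
    of the two survivor sets and may be empty.
    """
    n = stats.n_retained

    def survivors(values: np.ndarray, alpha: float) -> np.ndarray:
        t = _trim_count(alpha, n)
        if n - 2 * t < 1:
            return np.empty(0, dtype=np.intp)
        order = np.argsort(values, kind="stable")
        return order[t:n - t]

    keep_m = survivors(stats.M, alpha_m)
    keep_a = survivors(stats.A, alpha_a)
    return np.intersect1d(keep_m, keep_a)


def pairwise_log_factor(stats: PairwiseMA, g_star: np.ndarray) -> float:
    """Precision-weighted mean of M over the surviving genes.

    Weights are the inverse delta-method variances, ``w = 1/var``;
    ``g_star`` holds positions into the retained-gene arrays of ``stats``
    (as returned by :func:`dual_trim`).
    """
    g_star = np.asarray(g_star, dtype=np.intp)
    if len(g_star) == 0:
        raise ValueError("empty gene set after trimming")
    w = 1.0 / stats.var[g_star]
    return float(np.sum(w * stats.M[g_star]) / np.sum(w))


def _pair_entry(stats: PairwiseMA, config: TrimConfig) -> tuple[float, float, float]:
    """(log2 factor, alpha_m, alpha_a) for one pair; may raise DegeneratePairError."""
    if config.fixed_alpha_m is not None:
        alpha_m = config.fixed_alpha_m
    else:
        if stats.n_retained < 3:
            raise DegeneratePairError("fewer than 3 genes for adaptive trimming")
        alpha_m, _ = optimal_alpha(stats.M, config.delta, config.alpha_cap)
    if config.fixed_alpha_a is not None:
        alpha_a = config.fixed_alpha_a
    else:
        if stats.n_retained < 3:
            raise DegeneratePairError("fewer than 3 genes for adaptive trimming")
        alpha_a, _ = optimal_alpha(stats.A, config.delta, config.alpha_cap)
    keep = dual_trim(stats, alpha_m, alpha_a)
    if len(keep) < config.min_genes_after_trim:
        raise DegeneratePairError(
            f"only {len(keep)} genes survive dual trimming "
            f"(min_genes_after_trim={config.min_genes_after_trim})"
        )
    return pairwise_log_factor(stats, keep), alpha_m, alpha_a


def factor_matrix(
    counts: CountMatrix, config: TrimConfig | None = None
) -> tuple[np.ndarray, dict[tuple[int, int], tuple[float, float]], list[tuple[int, int, str]]]:
    """All-pairs log2 scale-factor matrix.

    Entry ``[r][k]`` is the log2 normalization factor of sample ``k``
    against reference ``r``; the diagonal is zero. Degenerate pairs (too few
    genes before or after trimming) contribute a zero entry plus a warning
    record rather than an error.

    Returns ``(log2_factor_matrix, alpha_table, warnings)``.
    """
    if config is None:
        config = TrimConfig()
    n = counts.n_samples
    if n < 2:
        raise ValueError("normalization needs at least 2 samples")
    library_sizes(counts)  # fail fast on zero columns
    matrix = np.zeros((n, n))
    alpha_table: dict[tuple[int, int], tuple[float, float]] = {}
    warnings: list[tuple[int, int, str]] = []
    for r in range(n):
        for k in range(n):
            if r == k:
                continue
            try:
                stats = pairwise_ma(counts, k, r)
                entry, alpha_m, alpha_a = _pair_entry(stats, config)
            except DegeneratePairError as exc:
                warnings.append((r, k, str(exc)))
                continue
            matrix[r, k] = entry
            alpha_table[(r, k)] = (alpha_m, alpha_a)
    return matrix, alpha_table, warnings


def aggregate_factors(
    log2_factor_matrix: np.ndarray, config: TrimConfig | None = None
) -> np.ndarray:
    """Per-sample scale factors from the all-pairs matrix.

    The factor of sample ``k`` is the geometric mean, over references
    (rows, the self-reference contributing factor 1), of the per-pair
    factors in column ``k``. With ``renormalize_factors`` the factors are
    rescaled so that their product is 1.
    """
    if config is None:
        config = TrimConfig()
    m = np.asarray(log2_factor_matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"factor matrix must be square, got shape {m.shape}")
    if np.any(np.diag(m) != 0):
        raise ValueError("factor matrix diagonal must be exactly zero")
    log2_factors = m.mean(axis=0)
    if config.renormalize_factors:
        log2_factors = log2_factors - log2_factors.mean()
    return 2.0 ** log2_factors


def normalize(counts: CountMatrix, config: TrimConfig | None = None) -> NormalizationResult:
    """Run the full aTMM pipeline on a count matrix.

    Composes :func:`library_sizes`, :func:`factor_matrix` and
    :func:`aggregate_factors`; deterministic (the estimator has no random
    component).
    """
    if config is None:
        config = TrimConfig()
    sizes = library_sizes(counts)
    matrix, alpha_table, warnings = factor_matrix(counts, config)
    factors = aggregate_factors(matrix, config)
    return NormalizationResult(
        log2_factor_matrix=matrix,
        factors=factors,
        effective_library_sizes=sizes * factors,
        alpha_table=alpha_table,
        warnings=warnings,
        sample_ids=counts.sample_ids,
    )


def classic_tmm(
    counts: CountMatrix,
    ref: int = 0,
    alpha_m: float = 0.30,
    alpha_a: float = 0.05,
    min_genes_after_trim: int = 10,
) -> np.ndarray:
    """Fixed-trim, single-reference TMM factors (baseline mode).

    The reference sample's factor is 1; every other sample's factor is
    ``2**pairwise_log_factor`` after dual-trimming M at ``alpha_m`` (default
    30%) and A at ``alpha_a`` (default 5%) against the single reference.
    Degenerate pairs fall back to factor 1.
    """
    n = counts.n_samples
    if not (0 <= ref < n):
        raise ValueError(f"reference index {ref} out of range for {n} samples")
    factors = np.ones(n)
    for k in range(n):
        if k == ref:
            continue
        try:
            stats = pairwise_ma(counts, k, ref)
            keep = dual_trim(stats, alpha_m, alpha_a)
            if len(keep) < min_genes_after_trim:
                raise DegeneratePairError("too few genes after trimming")
            factors[k] = 2.0 ** pairwise_log_factor(stats, keep)
        except DegeneratePairError:
            factors[k] = 1.0
    return factors
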