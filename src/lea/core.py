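"""KNN Local Enrichment Analysis (LEA) in class-probability space.

For every cell, LEA probes the k nearest neighbors in the original
class-probability space (not in any 2-D embedding) and tests the
neighborhood for:

* **discrete** enrichment of a condition X — the upper tail of a
  hypergeometric distribution: ``p = P(H >= n)`` with population N (all
  cells in the analysis), K cells of condition X, k draws (the
  neighborhood) and n observed X-cells among the neighbors;
* **continuous** association with a per-donor variable — the per-donor
  neighborhood fractions are rank-correlated (Spearman) with the variable
  across donors, and the two-sided significance of the correlation is the
  per-cell p-value.

The resulting p is assigned back to the center cell, Bonferroni-corrected
by the number of cells (= tests), and summarized as the signed score
``-log10(p) * sign`` (sign = +1 for discrete enrichment, correlation sign
for continuous).  A label-randomization null on the summed enrichment
calibrates whole-map significance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "REALMIN",
    "NeighborhoodIndex",
    "EnrichmentResult",
    "NullSummary",
    "build_knn",
    "lea_discrete",
    "lea_continuous",
    "adjust_pvalues",
    "signed_significance",
    "randomization_null",
]

#: smallest positive normal double; p-values are floored here before log10,
#: so the largest attainable signed score is -log10(REALMIN) ~ 307.65
REALMIN = float(np.finfo(np.float64).tiny)

MAHALANOBIS_RIDGE = 1e-8
_EXACT_SPEARMAN_MAX_DONORS = 9  # d! enumeration kept below 9! = 362,880


# ---------------------------------------------------------------------------
# containers


@dataclass
class NeighborhoodIndex:
    """Exact k-nearest-neighbor index over a probability matrix.

    ``neighbor_ids[i]`` holds the row indices of the k nearest other cells
    of cell i (the center cell is excluded from its own neighborhood).
    Distance ties are broken by ascending cell row index.
    """

    k: int
    metric: str
    neighbor_ids: np.ndarray  # N x k int
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        n, k = self.neighbor_ids.shape
        if k != self.k:
            raise ValueError("neighbor_ids width does not match k")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match neighbor rows")

    @property
    def n_cells(self) -> int:
        return self.neighbor_ids.shape[0]


@dataclass
class EnrichmentResult:
    """Per-cell LEA output.

    ``table`` columns: cell_id, n_in_neighborhood (discrete) or rho
    (continuous), p, p_adjust, signed_score.  ``p_adjust`` is the
    Bonferroni correction of ``p`` by the number of cells.
    """

    table: pd.DataFrame
    condition: str
    k: int
    metric: str
    kind: str  # "discrete" | "continuous"

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    @property
    def p_adjust(self) -> np.ndarray:
        return self.table["p_adjust"].to_numpy()

    @property
    def signed_score(self) -> np.ndarray:
        return self.table["signed_score"].to_numpy()

    def write(self, path, delimiter: str = "\t") -> None:
        self.table.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


@dataclass
class NullSummary:
    """Observed sum-enrichment against a label-randomization null."""

    observed: float
    null_sums: np.ndarray
    p_ttest: float | None
    p_empirical: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        self.null_sums = np.asarray(self.null_sums, dtype=float)
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


# ---------------------------------------------------------------------------
# neighborhoods


def _mahalanobis_vi(values: np.ndarray) -> np.ndarray:
    """Inverse covariance for Mahalanobis distances on simplex-valued rows.

    Probability rows sum to 1, so the covariance is rank-deficient; a small
    ridge plus pseudo-inverse keeps the metric defined on the simplex.
    """
    cov = np.cov(values, rowvar=False)
    rank = np.linalg.matrix_rank(cov)
    if rank < cov.shape[0]:
        warnings.warn(
            f"covariance is rank-deficient ({rank}/{cov.shape[0]}); "
            "using ridge pseudo-inverse for Mahalanobis distances",
            stacklevel=3,
        )
    return np.linalg.pinv(cov + MAHALANOBIS_RIDGE * np.eye(cov.shape[0]))


def build_knn(pm, k: int, metric: str = "euclidean", chunk: int = 1024) -> NeighborhoodIndex:
    """Exact KNN on the raw probability rows.

    Distances are computed exhaustively in row chunks and sorted with a
    stable sort, so ties are broken by ascending cell index and the result
    is independent of chunking.  ``metric`` is ``"euclidean"`` (default) or
    ``"mahalanobis"`` (ridge pseudo-inverse covariance).
    """
    values = np.asarray(pm.values, dtype=float)
    cell_ids = np.asarray(pm.cell_ids)
    n = values.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, N-1] = [1, {n - 1}], got {k}")
    kwargs = {}
    if metric == "mahalanobis":
        kwargs["VI"] = _mahalanobis_vi(values)
    elif metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(values[start:stop], values, metric=metric, **kwargs)
        rows = np.arange(start, stop)
        d[rows - start, rows] = np.inf  # exclude the center cell
        order = np.argsort(d, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return NeighborhoodIndex(k=k, metric=metric, neighbor_ids=out, cell_ids=cell_ids)


# ---------------------------------------------------------------------------
# shared arithmetic


def adjust_pvalues(p: np.ndarray, n_tests: int) -> np.ndarray:
    """Bonferroni: ``min(1, p * n_tests)`` elementwise."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * n_tests)


def signed_significance(p, sign) -> np.ndarray | float:
    """``-log10(max(p, realmin)) * sign`` — the per-cell map value."""
    p_arr = np.maximum(np.asarray(p, dtype=float), REALMIN)
    out = -np.log10(p_arr) * np.asarray(sign, dtype=float)
    return float(out) if out.ndim == 0 else out


def _align_labels(idx: NeighborhoodIndex, labels) -> np.ndarray:
    """Per-cell labels as an array aligned to the index rows."""
    if isinstance(labels, pd.Series):
        aligned = labels.reindex(idx.cell_ids)
        if aligned.isna().any():
            missing = idx.cell_ids[aligned.isna().to_numpy()][:10]
            raise ValueError(f"labels missing for cells: {list(missing)}")
        return aligned.to_numpy()
    arr = np.asarray(labels)
    if len(arr) != idx.n_cells:
        raise ValueError("labels must cover all indexed cells")
    return arr


# ---------------------------------------------------------------------------
# discrete LEA


def _hypergeom_tail_table(n_total: int, n_success: int, k_draws: int) -> np.ndarray:
    """``P(H >= n)`` for n = 0..k, H ~ Hypergeom(n_total, n_success, k_draws)."""
    ns = np.arange(k_draws + 1)
    return np.clip(stats.hypergeom.sf(ns - 1, n_total, n_success, k_draws), REALMIN, 1.0)


def lea_discrete(
    idx: NeighborhoodIndex,
    labels,
    condition,
    n_tests: int | None = None,
) -> EnrichmentResult:
    """Hypergeometric neighborhood enrichment for one discrete condition.

    Parameters
    ----------
    idx : precomputed neighborhood index.
    labels : per-cell condition labels (array aligned to ``idx.cell_ids``
        or a cell_id-indexed Series).
    condition : the condition X tested for local over-representation.
    n_tests : Bonferroni divisor; defaults to the number of cells.

    Per cell, ``p = P(H >= n)`` where n is the number of X-cells among the
    k neighbors, H ~ Hypergeometric(N cells, K X-cells, k draws).
    """
    lab = _align_labels(idx, labels)
    is_x = lab == condition
    n_cells = idx.n_cells
    k_total = int(is_x.sum())
    if k_total == 0:
        raise ValueError(f"condition {condition!r} absent from labels")
    n_in = is_x[idx.neighbor_ids].sum(axis=1)
    p = _hypergeom_tail_table(n_cells, k_total, idx.k)[n_in]
    p_adj = adjust_pvalues(p, n_tests if n_tests is not None else n_cells)
    table = pd.DataFrame(
        {
            "cell_id": idx.cell_ids,
            "n_in_neighborhood": n_in,
            "p": p,
            "p_adjust": p_adj,
            "signed_score": signed_significance(p, 1.0),
        }
    )
    return EnrichmentResult(table, str(condition), idx.k, idx.metric, "discrete")


# ---------------------------------------------------------------------------
# continuous LEA


def _donor_fractions(
    idx: NeighborhoodIndex, donor_codes: np.ndarray, n_donors: int, normalize: str
) -> np.ndarray:
    """N x D per-donor neighborhood composition.

    ``normalize="k"`` (default) divides each donor's neighbor count by k —
    the literal neighborhood fraction.  ``normalize="donor"`` divides by
    that donor's total cell count instead, for unequal donor sampling; the
    two are rank-equivalent when donors contribute equal cell numbers.
    Neighbors with code -1 (donors excluded from the analysis, e.g. for a
    missing covariate) are not counted in any column.
    """
    n = idx.n_cells
    counts = np.zeros((n, n_donors), dtype=float)
    nbr_codes = donor_codes[idx.neighbor_ids]
    rows = np.repeat(np.arange(n), idx.k)
    flat = nbr_codes.ravel()
    valid = flat >= 0
    np.add.at(counts, (rows[valid], flat[valid]), 1.0)
    if normalize == "k":
        return counts / idx.k
    if normalize == "donor":
        totals = np.bincount(donor_codes[donor_codes >= 0], minlength=n_donors).astype(float)
        return counts / np.maximum(totals, 1.0)
    raise ValueError(f"unknown normalize mode {normalize!r}")


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1, method="average")


def _standardize_rows(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row z-scores and a mask of zero-variance rows (left as zeros)."""
    mean = r.mean(axis=-1, keepdims=True)
    sd = r.std(axis=-1, keepdims=True)
    degenerate = sd[..., 0] == 0
    z = np.where(sd > 0, (r - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, degenerate


def _spearman_rho(fractions: np.ndarray, variable: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row Spearman rho of fractions against the variable.

    Pearson correlation of midranks, which handles ties in the fractions
    (frequent: neighborhood counts are small integers over k).
    Zero-variance rows get rho = 0 and are reported degenerate.
    """
    d = fractions.shape[-1]
    rf, degen_f = _standardize_rows(_rank_rows(fractions))
    rv, degen_v = _standardize_rows(_rank_rows(variable[None, :]))
    rho = (rf @ rv[0]) / d
    degenerate = degen_f | bool(degen_v[0])
    return np.clip(rho, -1.0, 1.0), degenerate


def _spearman_p_approx(rho: np.ndarray, d: int) -> np.ndarray:
    """Two-sided p via the t approximation with d - 2 degrees of freedom."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((d - 2) / np.maximum(1.0 - rho**2, 1e-300))
    return np.clip(2.0 * stats.t.sf(np.abs(t), d - 2), REALMIN, 1.0)


def _spearman_p_exact(fractions: np.ndarray, variable: np.ndarray, chunk: int = 256) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact two-sided permutation p by full enumeration of the d! orderings.

    Returns (rho, p, degenerate).  The permutation distribution conditions
    on the observed tie structure of both vectors, so ties are handled
    without approximation.
    """
    d = fractions.shape[-1]
    perms = np.array(list(itertools.permutations(range(d))), dtype=np.int64)
    rv = _rank_rows(variable[None, :])[0]
    rv_perm, degen_v = _standardize_rows(rv[perms])
    rf, degen_f = _standardize_rows(_rank_rows(fractions))
    n_cells = rf.shape[0]
    rho = np.empty(n_cells)
    p = np.empty(n_cells)
    for start in range(0, n_cells, chunk):
        stop = min(start + chunk, n_cells)
        rho_all = (rf[start:stop] @ rv_perm.T) / d  # cells x d!
        rho_obs = (rf[start:stop] @ rv_perm[0]) / d  # identity permutation first
        exceed = np.abs(rho_all) >= np.abs(rho_obs)[:, None] - 1e-12
        rho[start:stop] = rho_obs
        p[start:stop] = exceed.mean(axis=1)
    degenerate = degen_f | bool(degen_v[0])
    rho[degenerate] = 0.0
    p[degenerate] = 1.0
    return np.clip(rho, -1.0, 1.0), np.clip(p, REALMIN, 1.0), degenerate


def _continuous_pvalues(
    fractions: np.ndarray, variable: np.ndarray, method: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rho, two-sided p, degenerate mask) for each fraction row."""
    d = len(variable)
    if method == "auto":
        method = "exact" if d <= _EXACT_SPEARMAN_MAX_DONORS else "approx"
    if method == "exact":
        return _spearman_p_exact(fractions, variable)
    if method != "approx":
        raise ValueError(f"unknown Spearman method {method!r}")
    rho, degenerate = _spearman_rho(fractions, variable)
    p = _spearman_p_approx(rho, d)
    rho = np.where(degenerate, 0.0, rho)
    p = np.where(degenerate, 1.0, p)
    return rho, p, degenerate


def lea_continuous(
    idx: NeighborhoodIndex,
    donor_of_cell,
    variable: Mapping | pd.Series,
    method: str = "auto",
    normalize: str = "k",
    n_tests: int | None = None,
) -> EnrichmentResult:
    """Rank-correlation association of neighborhoods with a donor variable.

    Per cell, the per-donor neighborhood fractions are Spearman-correlated
    with ``variable`` across donors; the two-sided significance of the
    correlation, assigned to the center cell, is the LEA p-value and the
    signed score carries the correlation sign.

    Cells of donors with a missing variable value are excluded from the
    analysis population entirely (fractions, tests and correction all run
    on the retained subset).  ``method``: ``"exact"`` enumerates all d!
    orderings (default up to 9 donors), ``"approx"`` uses the t
    approximation with d - 2 df (default from 10 donors).
    """
    donors = _align_labels(idx, donor_of_cell)
    var = pd.Series(variable).dropna().astype(float)
    usable = pd.Index(var.index)
    if len(usable) < 3:
        raise ValueError(f"need >= 3 donors with a non-missing variable, got {len(usable)}")
    if float(var.std()) == 0.0:
        raise ValueError("tested variable is constant across donors")
    # donors without the variable are excluded per-analysis: their cells are
    # neither a fraction column nor counted among any neighborhood's donors
    uniques = usable.intersection(pd.Index(donors).unique()).sort_values()
    if len(uniques) < 3:
        raise ValueError(f"need >= 3 usable donors with cells, got {len(uniques)}")
    codes = uniques.get_indexer(pd.Index(donors))
    variable_by_code = var.reindex(uniques).to_numpy()
    fractions = _donor_fractions(idx, codes, len(uniques), normalize)
    rho, p, degenerate = _continuous_pvalues(fractions, variable_by_code, method)
    p_adj = adjust_pvalues(p, n_tests if n_tests is not None else idx.n_cells)
    table = pd.DataFrame(
        {
            "cell_id": idx.cell_ids,
            "rho": rho,
            "p": p,
            "p_adjust": p_adj,
            "signed_score": signed_significance(p, np.sign(rho)),
            "degenerate": degenerate,
        }
    )
    name = variable.name if isinstance(variable, pd.Series) and variable.name else "variable"
    return EnrichmentResult(table, str(name), idx.k, idx.metric, "continuous")


# ---------------------------------------------------------------------------
# randomization null


def _sum_enrichment_discrete(
    idx: NeighborhoodIndex, lab: np.ndarray, conditions: Sequence, n_tests: int
) -> float:
    """Sum over all cells and conditions of -log10(Bonferroni-adjusted p)."""
    total = 0.0
    n_cells = idx.n_cells
    nbr_lab = lab[idx.neighbor_ids]
    for cond in conditions:
        k_total = int((lab == cond).sum())
        if k_total == 0:
            continue
        tab = _hypergeom_tail_table(n_cells, k_total, idx.k)
        tab = np.maximum(np.minimum(tab * n_tests, 1.0), REALMIN)
        n_in = (nbr_lab == cond).sum(axis=1)
        total += float(-np.log10(tab[n_in]).sum())
    return total


def _sum_enrichment_continuous(
    fractions: np.ndarray, variable: np.ndarray, method: str, n_tests: int
) -> float:
    _, p, _ = _continuous_pvalues(fractions, variable, method)
    p_adj = np.maximum(np.minimum(p * n_tests, 1.0), REALMIN)
    return float(-np.log10(p_adj).sum())


def randomization_null(
    idx: NeighborhoodIndex,
    labels=None,
    conditions: Sequence | None = None,
    donor_of_cell=None,
    variable=None,
    method: str = "auto",
    normalize: str = "k",
    n_perm: int = 2000,
    seed: int = 0,
) -> NullSummary:
    """Label-randomization null for the summed LEA enrichment.

    The observed statistic is the sum over all cells (and, for discrete
    analyses, over all tested conditions) of ``-log10(adjusted p)``.  The
    null randomizes labels at the cell level (discrete) or permutes the
    variable across donors (continuous), recomputing the identical
    statistic ``n_perm`` times.  Significance is a one-sample one-sided
    t-test of the null sums against the observed value (alternative: null
    mean below observed); the empirical permutation p-value
    ``(1 + #{null >= observed}) / (n_perm + 1)`` is reported alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n_tests = idx.n_cells
    if labels is not None:
        lab = _align_labels(idx, labels)
        conds = list(pd.unique(lab)) if conditions is None else list(conditions)
        observed = _sum_enrichment_discrete(idx, lab, conds, n_tests)
        null_sums = np.empty(n_perm)
        for i in range(n_perm):
            null_sums[i] = _sum_enrichment_discrete(idx, rng.permutation(lab), conds, n_tests)
    elif variable is not None:
        if donor_of_cell is None:
            raise ValueError("continuous null needs donor_of_cell")
        donors = _align_labels(idx, donor_of_cell)
        var = pd.Series(variable).dropna().astype(float)
        uniques = pd.Index(var.index).intersection(pd.Index(donors).unique()).sort_values()
        if len(uniques) < 3:
            raise ValueError(f"need >= 3 usable donors with cells, got {len(uniques)}")
        codes = uniques.get_indexer(pd.Index(donors))
        v = var.reindex(uniques).to_numpy()
        fractions = _donor_fractions(idx, codes, len(uniques), normalize)
        observed = _sum_enrichment_continuous(fractions, v, method, n_tests)
        null_sums = np.empty(n_perm)
        for i in range(n_perm):
            null_sums[i] = _sum_enrichment_continuous(fractions, rng.permutation(v), method, n_tests)
    else:
        raise ValueError("provide labels (discrete) or variable (continuous)")

    p_emp = (1.0 + float((null_sums >= observed).sum())) / (n_perm + 1.0)
    if np.ptp(null_sums) == 0.0:
        warnings.warn(
            "constant null sums: t-test undefined, reporting empirical p only",
            stacklevel=2,
        )
        p_t = None
    else:
        res = stats.ttest_1samp(null_sums, popmean=observed, alternative="less")
        p_t = float(max(res.pvalue, REALMIN))
    return NullSummary(observed, null_sums, p_t, p_emp, n_perm, seed)
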