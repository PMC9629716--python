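"""Phenotype-to-transcriptome association and companion statistics.

Builds on continuous LEA: a gene's per-donor bulk abundance is the
continuous variable, so every cell receives a signed significance for the
association between its local phenotype neighborhood and that transcript.
Pathway-level summaries come in two flavours — a per-cell two-sample
t-test of in-pathway versus out-of-pathway gene scores, and a
hypergeometric overlap test of a pathway with the top positively
associated genes.  Also here: the AROC consistency benchmark, the signed
median-ratio group statistic, and per-well percentile-bin testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .core import (
    REALMIN,
    EnrichmentResult,
    NeighborhoodIndex,
    adjust_pvalues,
    lea_continuous,
    signed_significance,
)
from .datamodel import ExpressionTable, PathwayAnnotation

__all__ = [
    "PathwayScore",
    "gene_association",
    "gene_association_map",
    "pathway_ttest",
    "pathway_hypergeom",
    "benchmark_aroc",
    "signed_group_difference",
    "binned_feature_association",
]

#: -log10(p) > 1.3, i.e. p < 0.05 — default cutoff for calling a cell
#: positively / negatively associated when splitting by signed score
ASSOCIATION_CUTOFF = 1.3


# ---------------------------------------------------------------------------
# gene-level LEA


def gene_association(
    idx: NeighborhoodIndex,
    donor_of_cell,
    expr: ExpressionTable,
    gene: str,
    **kwargs,
) -> EnrichmentResult:
    """Continuous LEA with a gene's per-donor bulk abundance as variable.

    A gene constant across donors carries no association signal; it yields
    rho = 0, p = 1 for every cell rather than an error.
    """
    variable = expr.gene(gene)  # KeyError if absent
    if float(variable.std()) == 0.0:
        n = idx.n_cells
        table = pd.DataFrame(
            {
                "cell_id": idx.cell_ids,
                "rho": np.zeros(n),
                "p": np.ones(n),
                "p_adjust": np.ones(n),
                "signed_score": np.zeros(n),
                "degenerate": np.ones(n, dtype=bool),
            }
        )
        return EnrichmentResult(table, str(gene), idx.k, idx.metric, "continuous")
    return lea_continuous(idx, donor_of_cell, variable, **kwargs)


def gene_association_map(
    idx: NeighborhoodIndex,
    donor_of_cell,
    expr: ExpressionTable,
    genes: Sequence[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Cells x genes matrix of signed association scores.

    Genes constant across donors get score 0 everywhere (no association is
    estimable); all other entries are finite by the realmin floor.
    """
    gene_list = list(expr.genes) if genes is None else list(genes)
    out = np.zeros((idx.n_cells, len(gene_list)))
    for j, g in enumerate(gene_list):
        variable = expr.gene(g)
        if float(variable.std()) == 0.0:
            continue
        res = lea_continuous(idx, donor_of_cell, variable, **kwargs)
        out[:, j] = res.signed_score
    return pd.DataFrame(out, index=pd.Index(idx.cell_ids, name="cell_id"), columns=gene_list)


# ---------------------------------------------------------------------------
# pathway summaries


@dataclass
class PathwayScore:
    """Per-cell pathway statistics from the t-test variant.

    ``p``, ``direction`` and ``signed_score`` are cells x pathways frames;
    direction is sign(mean in-pathway score - mean background score).
    """

    p: pd.DataFrame
    direction: pd.DataFrame
    signed_score: pd.DataFrame
    skipped: list[str]


def _welch_rowwise(x_in: np.ndarray, x_out: np.ndarray, equal_var: bool) -> np.ndarray:
    """Two-sample two-tailed t-test p per row; degenerate rows give p = 1."""
    n1, n2 = x_in.shape[1], x_out.shape[1]
    m1, m2 = x_in.mean(axis=1), x_out.mean(axis=1)
    v1 = x_in.var(axis=1, ddof=1)
    v2 = x_out.var(axis=1, ddof=1)
    if equal_var:
        sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, n1 + n2 - 2, dtype=float)
    else:
        a, b = v1 / n1, v2 / n2
        se2 = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1.0))
    p = np.where(se2 == 0, np.where(m1 == m2, 1.0, REALMIN), p)
    return np.clip(p, REALMIN, 1.0)


def pathway_ttest(
    gene_scores: pd.DataFrame,
    annotation: PathwayAnnotation,
    equal_var: bool = False,
) -> PathwayScore:
    """Per-cell pathway significance: in-pathway vs all other gene scores.

    ``gene_scores`` is a cells x genes frame of signed LEA scores (see
    :func:`gene_association_map`).  For each cell and pathway, the scores
    of the annotated genes are compared against the scores of all other
    measured genes with a two-tailed two-sample t-test (Welch by default;
    ``equal_var=True`` for the pooled-variance form) and directionality is
    the sign of the difference of the means.  Pathways with fewer than two
    measured genes on either side are skipped with a warning.
    """
    genes = pd.Index(gene_scores.columns)
    x = gene_scores.to_numpy(dtype=float)
    cols_p, cols_dir, kept, skipped = [], [], [], []
    for pid, members in annotation.items():
        mask = genes.isin(members)
        if mask.sum() < 2 or (~mask).sum() < 2:
            skipped.append(pid)
            continue
        p = _welch_rowwise(x[:, mask], x[:, ~mask], equal_var)
        direction = np.sign(x[:, mask].mean(axis=1) - x[:, ~mask].mean(axis=1))
        cols_p.append(p)
        cols_dir.append(direction)
        kept.append(pid)
    if skipped:
        warnings.warn(
            f"{len(skipped)} pathways skipped (<2 measured genes in or out): "
            + ", ".join(skipped[:5]),
            stacklevel=2,
        )
    p_df = pd.DataFrame(np.column_stack(cols_p) if kept else np.empty((len(x), 0)),
                        index=gene_scores.index, columns=kept)
    d_df = pd.DataFrame(np.column_stack(cols_dir) if kept else np.empty((len(x), 0)),
                        index=gene_scores.index, columns=kept)
    s_df = pd.DataFrame(
        signed_significance(p_df.to_numpy(), d_df.to_numpy()) if kept else np.empty((len(x), 0)),
        index=gene_scores.index,
        columns=kept,
    )
    return PathwayScore(p_df, d_df, s_df, skipped)


def pathway_hypergeom(
    gene_scores: pd.Series,
    annotation: PathwayAnnotation,
    percentile: float = 0.95,
    positive_only: bool = True,
) -> pd.DataFrame:
    """Hypergeometric overlap of pathways with the top associated genes.

    ``gene_scores`` maps gene -> association score over a cell set (e.g.
    the mean signed score across the cells of interest).  The top set is
    genes scoring above the ``percentile`` quantile computed over the
    positively associated genes (``positive_only=False`` computes the
    quantile over all genes instead).  Per pathway, the upper-tail
    hypergeometric p of the observed overlap is computed with all measured
    genes as the population, then Bonferroni-corrected over pathways.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    scores = gene_scores.astype(float)
    n_genes = len(scores)
    pool = scores[scores > 0] if positive_only else scores
    if len(pool) == 0:
        top: set[str] = set()
    else:
        thr = float(np.quantile(pool.to_numpy(), percentile))
        top = set(scores.index[scores > thr])
    rows = []
    universe = set(map(str, scores.index))
    for pid, members in annotation.items():
        measured = members & universe
        overlap = len(measured & top)
        if len(top) == 0 or len(measured) == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, n_genes, len(measured), len(top)))
        rows.append((pid, len(measured), overlap, max(p, REALMIN)))
    out = pd.DataFrame(rows, columns=["pathway_id", "n_measured", "overlap", "p"])
    out["p_adjust"] = adjust_pvalues(out["p"].to_numpy(), len(out)) if len(out) else []
    return out


# ---------------------------------------------------------------------------
# benchmarks and group statistics


def benchmark_aroc(scores, truth) -> float:
    """Rank-based AROC between a per-cell score and binary marker truth.

    Ties count half; equals the Mann-Whitney U statistic normalized by the
    number of positive-negative pairs.
    """
    y = np.asarray(truth).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("AROC undefined: truth contains a single class")
    return float(roc_auc_score(y, s))


def signed_group_difference(
    feature,
    pos_mask,
    neg_mask,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Signed median-ratio significance between two cell groups.

    p is a two-tailed t-test (Welch default) between the feature values of
    the positive and negative groups; the returned score is
    ``-log10(p) * sign(1 - median(pos) / median(neg))``.  Returns
    ``(score, p)``.
    """
    x = np.asarray(feature, dtype=float)
    pos_idx = np.asarray(pos_mask)
    neg_idx = np.asarray(neg_mask)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("both groups must be non-empty")
    pos = x[pos_idx]
    neg = x[neg_idx]
    med_neg = float(np.median(neg))
    if med_neg == 0.0:
        raise ValueError("median of the negative group is zero: sign undefined")
    res = stats.ttest_ind(pos, neg, equal_var=equal_var)
    p = float(res.pvalue)
    if np.isnan(p):  # both groups constant
        p = 1.0
    p = min(max(p, REALMIN), 1.0)
    sign = float(np.sign(1.0 - float(np.median(pos)) / med_neg))
    return float(signed_significance(p, sign)), p


@dataclass
class BinAssociation:
    """Per-bin means across wells with significance against the last bin."""

    bins: pd.DataFrame  # bin, mean, sd, p (vs reference bin)
    well_means: pd.DataFrame  # wells x bins
    skipped_wells: list


def _percentile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per value; ties assigned to the lower bin."""
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, values, side="left")


def binned_feature_association(
    cells: pd.DataFrame,
    bin_feature: str,
    response_feature: str,
    well_col: str = "well_id",
    n_bins: int = 10,
    equal_var: bool = False,
) -> BinAssociation:
    """Per-well percentile-bin analysis of one feature against another.

    Within each well, cells are assigned to ``n_bins`` equal-frequency bins
    of ``bin_feature`` and the mean ``response_feature`` is taken per bin.
    Each bin's well means are then compared to those of the reference
    (last, highest) bin with a two-tailed t-test across replicate wells.
    Wells with fewer cells than bins are skipped with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    wells = cells[well_col].unique()
    if len(wells) < 2:
        raise ValueError("need >= 2 wells")
    rows, skipped = {}, []
    for well, grp in cells.groupby(well_col, sort=True):
        if len(grp) < n_bins:
            skipped.append(well)
            continue
        b = _percentile_bins(grp[bin_feature].to_numpy(dtype=float), n_bins)
        resp = grp[response_feature].to_numpy(dtype=float)
        rows[well] = pd.Series(resp).groupby(b).mean().reindex(range(n_bins))
    if skipped:
        warnings.warn(f"wells skipped (fewer cells than bins): {skipped}", stacklevel=2)
    if len(rows) < 2:
        raise ValueError("fewer than 2 wells with enough cells to bin")
    wm = pd.DataFrame(rows).T  # wells x bins
    wm.index.name = well_col
    ref = wm.iloc[:, -1].to_numpy(dtype=float)
    out = []
    for b in range(n_bins):
        vals = wm.iloc[:, b].to_numpy(dtype=float)
        if b == n_bins - 1:
            p = 1.0
        else:
            p = float(stats.ttest_ind(vals, ref, equal_var=equal_var).pvalue)
            if np.isnan(p):
                p = 1.0
        out.append((b, float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1)), min(max(p, REALMIN), 1.0)))
    bins = pd.DataFrame(out, columns=["bin", "mean", "sd", "p"])
    return BinAssociation(bins, wm, skipped)
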