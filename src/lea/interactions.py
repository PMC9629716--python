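"""Radius-based spatial neighbor graphs and cell-type interaction scores.

Two cells interact when their nuclear centroids lie within a Euclidean
radius (default 40 px) in the same image site; pairs are pooled per well.
The interaction score for an unordered class pair (A, B) divides the
observed neighbor-pair count by its expectation under class-fraction
mixing, ``frac_A * frac_B * total interactions``, so ~1 means no spatial
preference.  Counting is done over ordered pairs for both the specific
and the total count, which makes the score exactly symmetric in (A, B)
and convention-stable (the shared factor 2 cancels).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datamodel import CellTable, ValidationError

__all__ = [
    "SpatialGraph",
    "build_spatial_graph",
    "interaction_scores",
    "aggregate_scores",
    "neighbor_class_counts",
]

DEFAULT_RADIUS_PX = 40.0


@dataclass
class SpatialGraph:
    """Unordered interacting cell pairs per well.

    ``pairs`` columns: well_id, site_id, cell_a, cell_b (cell ids, each
    unordered pair listed once), distance.  ``cells`` keeps every cell of
    the input (including non-interacting ones) with its well, for the
    class-fraction denominators.
    """

    pairs: pd.DataFrame
    cells: pd.DataFrame  # cell_id, well_id
    radius: float


def build_spatial_graph(cells: CellTable | pd.DataFrame, radius: float = DEFAULT_RADIUS_PX) -> SpatialGraph:
    """All centroid pairs within ``radius`` px, per site, pooled per well.

    Sites are independent pixel coordinate frames, so neighbor search never
    crosses a site boundary.  The distance comparison is inclusive (<=).
    """
    df = cells.df if isinstance(cells, CellTable) else cells
    for col in ("cell_id", "well_id", "site_id", "x", "y"):
        if col not in df.columns:
            raise ValidationError(f"spatial graph needs column {col!r}")
    bad = df[df[["x", "y"]].isna().any(axis=1)]
    if len(bad):
        raise ValidationError(
            f"cells with missing coordinates: {list(bad['cell_id'][:10])}"
        )
    rows = []
    for (well, site), grp in df.groupby(["well_id", "site_id"], sort=True):
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        ids = grp["cell_id"].to_numpy()
        if len(grp) < 2:
            continue
        tree = cKDTree(xy)
        pairs = tree.query_pairs(r=radius, output_type="ndarray")
        if len(pairs) == 0:
            continue
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "well_id": well,
                    "site_id": site,
                    "cell_a": ids[pairs[:, 0]],
                    "cell_b": ids[pairs[:, 1]],
                    "distance": d,
                }
            )
        )
    pairs_df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["well_id", "site_id", "cell_a", "cell_b", "distance"])
    )
    return SpatialGraph(pairs_df, df[["cell_id", "well_id"]].copy(), float(radius))


def interaction_scores(
    graph: SpatialGraph,
    class_labels: Mapping | pd.Series,
    classes: Sequence | None = None,
    total_convention: str = "pairs",
) -> pd.DataFrame:
    """Normalized interaction score per well for every unordered class pair.

    ``specific(A, B)`` counts ordered neighbor pairs (a in A, b in B);
    ``total`` counts all ordered neighbor pairs (= 2x the unordered pairs)
    under the default ``total_convention="pairs"``, or the number of
    distinct interacting cells under ``total_convention="cells"``.  The
    score is ``specific / (frac_A * frac_B * total)`` with class fractions
    over all cells in the well.  Exactly C(C+1)/2 rows per well; undefined
    scores (no interactions, or an absent class) are NaN, never 0.
    """
    if total_convention not in ("pairs", "cells"):
        raise ValueError(f"unknown total_convention {total_convention!r}")
    labels = pd.Series(class_labels)
    class_list = sorted(pd.unique(labels)) if classes is None else list(classes)
    code = {c: i for i, c in enumerate(class_list)}
    n_cls = len(class_list)
    out = []
    cells_by_well = dict(tuple(graph.cells.groupby("well_id", sort=True)))
    pairs_by_well = dict(tuple(graph.pairs.groupby("well_id", sort=True)))
    for well, wcells in cells_by_well.items():
        lab = labels.reindex(wcells["cell_id"])
        if lab.isna().any():
            raise ValueError(f"class labels missing for cells in well {well!r}")
        frac = lab.value_counts(normalize=True).reindex(class_list).fillna(0.0)
        wpairs = pairs_by_well.get(well)
        ordered = np.zeros((n_cls, n_cls), dtype=float)
        n_interacting_cells = 0
        if wpairs is not None and len(wpairs):
            ca = labels.reindex(wpairs["cell_a"]).map(code).to_numpy()
            cb = labels.reindex(wpairs["cell_b"]).map(code).to_numpy()
            np.add.at(ordered, (ca, cb), 1.0)
            np.add.at(ordered, (cb, ca), 1.0)
            n_interacting_cells = len(
                set(wpairs["cell_a"]).union(wpairs["cell_b"])
            )
        total_ordered = float(ordered.sum())
        total = total_ordered if total_convention == "pairs" else float(n_interacting_cells)
        for a, b in combinations_with_replacement(range(n_cls), 2):
            specific = ordered[a, b] if a != b else ordered[a, a]
            fa, fb = float(frac.iloc[a]), float(frac.iloc[b])
            denom = fa * fb * total
            score = specific / denom if denom > 0 else np.nan
            out.append(
                (well, class_list[a], class_list[b], specific, total, fa, fb, score)
            )
    return pd.DataFrame(
        out,
        columns=["well_id", "class_a", "class_b", "specific", "total", "frac_a", "frac_b", "score"],
    )


def aggregate_scores(
    scores: pd.DataFrame,
    condition_of_well: Mapping,
    control: str,
) -> pd.DataFrame:
    """Replicate-mean, log2-transformed, control-normalized scores.

    Per condition and class pair: ``log2(mean score over replicate wells)
    - log2(mean over control wells)``.  NaN well scores are excluded from
    the means; a zero or undefined control mean leaves the pair NaN.
    """
    df = scores.copy()
    df["condition"] = df["well_id"].map(pd.Series(condition_of_well))
    if df["condition"].isna().any():
        missing = df.loc[df["condition"].isna(), "well_id"].unique()
        raise ValueError(f"wells without a condition: {list(missing[:10])}")
    if control not in set(df["condition"]):
        raise ValueError(f"control condition {control!r} has no wells")
    means = (
        df.groupby(["condition", "class_a", "class_b"])["score"]
        .mean()  # skips NaN wells
        .rename("mean_score")
        .reset_index()
    )
    ctrl = means[means["condition"] == control].set_index(["class_a", "class_b"])["mean_score"]
    with np.errstate(divide="ignore", invalid="ignore"):
        means["log2_mean"] = np.log2(means["mean_score"].to_numpy())
        ref = ctrl.reindex(means.set_index(["class_a", "class_b"]).index).to_numpy()
        means["log2_norm"] = means["log2_mean"] - np.log2(ref)
    means.loc[~np.isfinite(means["log2_norm"]), "log2_norm"] = np.nan
    return means


def neighbor_class_counts(
    graph: SpatialGraph,
    class_labels: Mapping | pd.Series,
    classes: Sequence | None = None,
) -> pd.DataFrame:
    """Per-cell count of spatial neighbors of each class.

    Exposes the multicellular context as per-cell scalar features, so the
    counts can be merged into a :class:`~lea.datamodel.CellTable` and fed
    to LEA like any other feature.
    """
    labels = pd.Series(class_labels)
    class_list = sorted(pd.unique(labels)) if classes is None else list(classes)
    cell_ids = graph.cells["cell_id"]
    pos = pd.Series(np.arange(len(cell_ids)), index=cell_ids)
    counts = np.zeros((len(cell_ids), len(class_list)), dtype=np.int64)
    if len(graph.pairs):
        code = {c: i for i, c in enumerate(class_list)}
        ia = pos.reindex(graph.pairs["cell_a"]).to_numpy()
        ib = pos.reindex(graph.pairs["cell_b"]).to_numpy()
        la = labels.reindex(graph.pairs["cell_a"]).map(code).to_numpy()
        lb = labels.reindex(graph.pairs["cell_b"]).map(code).to_numpy()
        np.add.at(counts, (ia, lb), 1)
        np.add.at(counts, (ib, la), 1)
    out = pd.DataFrame(counts, columns=[f"n_neighbors_{c}" for c in class_list])
    out.insert(0, "cell_id", cell_ids.to_numpy())
    return out
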