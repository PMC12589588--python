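"""Normalization, clustering and marker-based annotation of cells.

Two normalization protocols are supported: the high-plex route (scale each
cell's total to the pre-normalization median total, then log1p) and the
high-sensitivity route (total-count scaling only, no log).  Clustering is
PCA → kNN graph → Leiden community detection with an explicit seed.
Cluster annotation replaces manual marker inspection with a reproducible
scoring rule: each cluster receives the type whose marker set has the
highest mean scaled expression, with a margin rule that labels ambiguous
clusters "nan" (the analogue of manual doublet exclusion).  A per-cluster
score table is returned for review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellByGene, CellMap

__all__ = ["MarkerDictionary", "normalize", "cluster", "leiden_on_rows",
           "annotate", "rare_cell_call", "regroup"]


@dataclass
class MarkerDictionary:
    """type → marker genes, plus a fine → coarse label grouping."""

    markers: dict[str, list[str]]
    grouping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(len(v) == 0 for v in self.markers.values()):
            raise ValueError("marker lists must be non-empty")


def normalize(cbg: CellByGene, protocol: str = "hybiss") -> pd.DataFrame:
    """Per-cell total-count normalization.

    ``hybiss``: scale each cell's total to the median pre-normalization
    total, then log(1+x).  ``scrinshot``: total-count scaling only.
    """
    totals = cbg.totals().astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total cell present; run QC first")
    target = float(np.median(totals))
    dense = cbg.counts.toarray().astype(float)
    scaled = dense * (target / totals)[:, None]
    if protocol == "hybiss":
        scaled = np.log1p(scaled)
    elif protocol != "scrinshot":
        raise ValueError(f"unknown protocol {protocol!r}")
    return pd.DataFrame(scaled, index=cbg.cell_ids, columns=cbg.gene_ids)


def leiden_on_rows(X: np.ndarray, n_neighbors: int, resolution: float,
                   seed: int) -> np.ndarray:
    """Leiden community detection on a Euclidean kNN graph of the rows."""
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    n = X.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed), n_iterations=-1)
    return np.asarray(part.membership, dtype=int)


def cluster(norm: pd.DataFrame, n_neighbors: int = 20, resolution: float = 1.5,
            n_pcs: int = 7, seed: int = 0) -> np.ndarray:
    """Cluster cells: PCA to ``n_pcs`` (0 = use the matrix directly, as for
    subclustering), kNN graph, Leiden at the given resolution and seed.
    Returns contiguous integer labels."""
    X = norm.to_numpy(dtype=float)
    if n_pcs < 0:
        raise ValueError("n_pcs must be >= 0")
    if n_neighbors >= X.shape[0]:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={X.shape[0]}")
    if n_pcs > 0:
        from sklearn.decomposition import PCA

        n_pcs_eff = min(n_pcs, min(X.shape) - 1)
        X = PCA(n_components=n_pcs_eff, random_state=seed).fit_transform(X)
    # identical expression rows must land in the same cluster; duplicates
    # would otherwise fragment the kNN graph into arbitrary cliques
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    if len(uniq) == 1:
        return np.zeros(X.shape[0], dtype=int)
    labels = leiden_on_rows(uniq, min(n_neighbors, len(uniq) - 1),
                            resolution, seed)[inverse]
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def annotate(labels: np.ndarray, norm: pd.DataFrame, markers: MarkerDictionary,
             margin: float = 0.10) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each cluster the cell type whose markers score highest.

    Per gene, expression is min-max scaled across cells; a cluster's score
    for a type is the mean scaled expression of that type's markers in the
    cluster.  Clusters whose best score is within ``margin``×top of the
    runner-up — or non-positive — are labeled "nan".  Returns per-cell
    labels and the per-cluster score table.
    """
    if not markers.markers:
        raise ValueError("empty marker dictionary")
    X = norm.to_numpy(dtype=float)
    rng_ = X.max(axis=0) - X.min(axis=0)
    rng_[rng_ == 0] = 1.0
    scaled = (X - X.min(axis=0)) / rng_
    scaled = pd.DataFrame(scaled, index=norm.index, columns=norm.columns)

    clusters = np.unique(labels)
    scores = pd.DataFrame(index=clusters, columns=list(markers.markers), dtype=float)
    for t, genes in markers.markers.items():
        present = [g for g in genes if g in scaled.columns]
        if not present:
            scores[t] = np.nan
            continue
        per_cell = scaled[present].mean(axis=1).to_numpy()
        for c in clusters:
            scores.loc[c, t] = per_cell[labels == c].mean()

    cluster_label: dict[int, str] = {}
    for c in clusters:
        row = scores.loc[c].dropna().sort_values(ascending=False)
        if len(row) == 0 or row.iloc[0] <= 0:
            cluster_label[c] = "nan"
            continue
        if len(row) > 1 and (row.iloc[0] - row.iloc[1]) < margin * row.iloc[0]:
            cluster_label[c] = "nan"      # ambiguous: two types within margin
        else:
            cluster_label[c] = row.index[0]
    per_cell = pd.Series([cluster_label[c] for c in labels], index=norm.index,
                         name="type_label")
    return per_cell, scores


def rare_cell_call(cbg: CellByGene, rare_markers: list[str],
                   positivity: float = 0.20) -> pd.DataFrame:
    """Marker-positivity calling for rare cell types.

    For each rare marker gene g the threshold is ``positivity`` × (max count
    of g over cells); a cell is positive for g when its count strictly
    exceeds the threshold.  Returns a table (cell_id, marker) of positive
    calls; a cell appearing for ≥1 marker is a rare-cell candidate.
    """
    missing = set(rare_markers) - set(cbg.gene_ids.tolist())
    if missing:
        raise ValueError(f"rare markers not in panel: {sorted(missing)}")
    frame = cbg.to_frame()
    calls = []
    for g in rare_markers:
        col = frame[g]
        mx = col.max()
        if mx == 0:
            warnings.warn(f"rare marker {g} has zero counts everywhere")
        thr = positivity * mx
        pos = col[col > thr]
        calls.extend((cid, g) for cid in pos.index)
    return pd.DataFrame(calls, columns=["cell_id", "marker"])


def regroup(cellmap: CellMap, grouping: dict[str, str]) -> CellMap:
    """Replace fine type labels by coarse ones; "nan" stays "nan"."""
    df = cellmap.data.copy()
    labels = df["type_label"].astype(str)
    unmapped = sorted(set(labels) - set(grouping) - {"nan"})
    if unmapped:
        raise ValueError(f"labels missing from grouping: {unmapped}")
    df["type_label"] = labels.map(lambda t: "nan" if t == "nan" else grouping[t])
    return CellMap(df)
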