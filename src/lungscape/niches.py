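"""Cell-type neighborhood enrichment and kNN-composition niche discovery.

Each cell's microenvironment is its k (default 20) nearest neighbors within
the same sample.  Two complementary analyses are built on this graph:

* pairwise enrichment — for every type pair, the number of neighbor
  incidences is compared against a permutation null (type labels shuffled
  over fixed positions) and summarized as a z-score; pairs with z above a
  threshold (default 2) form the co-localization graph;
* niche discovery — the cells × types neighbor-composition matrix is
  normalized, log-transformed and Leiden-clustered; clusters smaller than a
  floor (default 50 cells) are unique microenvironments rather than general
  neighborhoods, so their cells are marked unassigned instead of deleted.

Condition contrasts on per-sample niche (or type) proportions use the
logit-transform / zero-replacement / Holm–Šídák multiple t-test protocol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from dataclasses import dataclass
from scipy.spatial import cKDTree
from scipy.special import logit
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .io import CellMap

__all__ = ["NeighborhoodComposition", "EnrichmentResult", "knn_indices",
           "composition_matrix", "pairwise_enrichment", "enrichment_graph",
           "niche_cluster", "apply_size_floor", "niche_condition_composition",
           "compare_conditions"]


def _sample_knn(xy: np.ndarray, ids: np.ndarray, k: int) -> np.ndarray:
    """Indices (local, row-aligned) of each cell's k nearest neighbors,
    self excluded; ties at the k-th distance break by cell id."""
    n = len(xy)
    if n <= k:
        raise ValueError(f"sample has {n} cells, need > k={k}")
    if n <= 3000:
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        out = np.empty((n, k), dtype=int)
        for i in range(n):
            order = np.lexsort((ids, d2[i]))
            out[i] = order[:k]
        return out
    tree = cKDTree(xy)
    _, idx = tree.query(xy, k=k + 1)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i][idx[i] != i][:k]
        out[i] = row
    return out


def knn_indices(cellmap: CellMap, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Global neighbor index array over the full cell map, computed
    per sample (no cross-sample neighbors).  Returns (neighbor indices
    (n, k), row order as positional indices into cellmap.data, sample codes)."""
    df = cellmap.data.reset_index(drop=True)
    nbrs = np.empty((len(df), k), dtype=int)
    sample_codes = pd.factorize(df["sample_id"])[0]
    for s in np.unique(sample_codes):
        pos = np.flatnonzero(sample_codes == s)
        sub = df.iloc[pos]
        try:
            local = _sample_knn(sub[["x", "y"]].to_numpy(float),
                                sub["cell_id"].to_numpy(), k)
        except ValueError as e:
            raise ValueError(f"sample {df['sample_id'].iloc[pos[0]]!r}: {e}") from e
        nbrs[pos] = pos[local]
    return nbrs, np.arange(len(df)), sample_codes


@dataclass
class NeighborhoodComposition:
    """Cells × types counts of each cell's k nearest neighbors."""

    counts: pd.DataFrame        # index: positional cell order; columns: types
    meta: pd.DataFrame          # cell_id, sample_id, condition (if present)
    k: int

    def __post_init__(self) -> None:
        row_sums = self.counts.to_numpy().sum(axis=1)
        if not (row_sums == self.k).all():
            raise ValueError("every composition row must sum to k")


def composition_matrix(cellmap: CellMap, k: int = 20) -> NeighborhoodComposition:
    """Count each cell's k nearest same-sample neighbors by type."""
    df = cellmap.data.reset_index(drop=True)
    nbrs, _, _ = knn_indices(cellmap, k)
    types, type_codes = np.unique(df["type_label"].astype(str), return_inverse=True)
    T = len(types)
    flat = type_codes[nbrs]                      # (n, k)
    counts = np.zeros((len(df), T), dtype=int)
    for t in range(T):
        counts[:, t] = (flat == t).sum(axis=1)
    meta_cols = [c for c in ("cell_id", "sample_id", "condition") if c in df.columns]
    return NeighborhoodComposition(
        pd.DataFrame(counts, columns=types), df[meta_cols].copy(), k)


@dataclass
class EnrichmentResult:
    """Permutation neighborhood-enrichment summary per type pair."""

    types: np.ndarray
    observed: pd.DataFrame      # symmetrized incidence counts
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    zscores: pd.DataFrame       # NaN where null sd = 0
    n_permutations: int
    seed: int


def pairwise_enrichment(cellmap: CellMap, k: int = 20, n_permutations: int = 1000,
                        seed: int = 0) -> EnrichmentResult:
    """Neighborhood enrichment z-scores against a label-permutation null.

    The observed statistic for (a, b) is the symmetrized count of
    (type-a cell, type-b neighbor) incidences in the per-sample kNN graph;
    the null permutes type labels over the fixed cell positions (within
    sample).
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    # canonical row order makes the result independent of input ordering
    # (the permutation stream then visits cells identically)
    df = (cellmap.data.sort_values(["sample_id", "cell_id"], kind="stable")
          .reset_index(drop=True))
    cellmap = CellMap(df)
    types = np.unique(df["type_label"].astype(str))
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    T = len(types)
    type_codes = pd.Categorical(df["type_label"].astype(str),
                                categories=types).codes.astype(int)
    nbrs, _, sample_codes = knn_indices(cellmap, k)

    def incidence(codes: np.ndarray) -> np.ndarray:
        src = np.repeat(codes, k)
        dst = codes[nbrs].ravel()
        m = np.bincount(src * T + dst, minlength=T * T).reshape(T, T)
        return m + m.T

    obs = incidence(type_codes)
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, T, T))
    perm = type_codes.copy()
    groups = [np.flatnonzero(sample_codes == s) for s in np.unique(sample_codes)]
    for p in range(n_permutations):
        for pos in groups:
            perm[pos] = type_codes[pos][rng.permutation(len(pos))]
        null[p] = incidence(perm)
    mean, sd = null.mean(axis=0), null.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    as_df = lambda m: pd.DataFrame(m, index=types, columns=types)
    return EnrichmentResult(types, as_df(obs), as_df(mean), as_df(sd), as_df(z),
                            n_permutations, seed)


def enrichment_graph(result: EnrichmentResult, threshold: float = 2.0) -> nx.Graph:
    """Co-localization graph: types as nodes, edges where z > threshold
    (strict).  Isolated nodes are retained."""
    g = nx.Graph()
    g.add_nodes_from(result.types)
    z = result.zscores
    for i, a in enumerate(result.types):
        for b in result.types[i:]:
            val = z.loc[a, b]
            if np.isfinite(val) and val > threshold:
                g.add_edge(a, b, z=float(val))
    return g


UNASSIGNED_NICHE = -1


def apply_size_floor(labels: np.ndarray, min_cluster_size: int) -> np.ndarray:
    """Relabel clusters contiguously by decreasing size; members of clusters
    strictly smaller than ``min_cluster_size`` become ``UNASSIGNED_NICHE``."""
    labels = np.asarray(labels)
    ids, sizes = np.unique(labels, return_counts=True)
    kept = ids[sizes >= min_cluster_size]
    if len(kept) == 0:
        raise ValueError(f"all niche clusters below the {min_cluster_size}-cell floor")
    order = kept[np.argsort(-sizes[np.isin(ids, kept)])]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap.get(l, UNASSIGNED_NICHE) for l in labels], dtype=int)


def niche_cluster(comp: NeighborhoodComposition, resolution: float = 1.0,
                  min_cluster_size: int = 50, seed: int = 0,
                  n_neighbors: int = 15) -> np.ndarray:
    """Cluster neighborhood compositions into niches.

    Rows are library-size normalized (a near no-op at fixed k, kept for
    variable-k modes), log1p-transformed and Leiden-clustered on a kNN
    graph.  Clusters with fewer than ``min_cluster_size`` members are
    unique microenvironments: their cells are labeled ``UNASSIGNED_NICHE``
    (-1) rather than dropped, conserving cell counts.  Remaining niches are
    relabeled contiguously by decreasing size.
    """
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    X = comp.counts.to_numpy(dtype=float)
    row_tot = X.sum(axis=1)
    X = np.log1p(X * (np.median(row_tot) / row_tot)[:, None])
    # Composition rows are heavily duplicated (k neighbors drawn from few
    # types), and duplicate rows would form disconnected cliques in a plain
    # cell-level kNN graph.  The graph is therefore built over the distinct
    # profiles, with edges weighted by multiplicity product and a Gaussian
    # distance decay, and communities are mapped back to cells.
    uniq, inverse, mult = np.unique(X, axis=0, return_inverse=True,
                                    return_counts=True)
    if len(uniq) == 1:
        labels = np.zeros(len(X), dtype=int)
    else:
        k_eff = min(n_neighbors, len(uniq) - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(uniq)
        dist, idx = nn.kneighbors(uniq)
        sigma = float(dist[:, 1:].mean()) + 1e-12
        edges: dict[tuple[int, int], float] = {}
        for i in range(len(uniq)):
            for d, j in zip(dist[i, 1:], idx[i, 1:]):
                key = (min(i, int(j)), max(i, int(j)))
                w = mult[i] * mult[j] * np.exp(-((d / sigma) ** 2))
                edges[key] = max(edges.get(key, 0.0), w)
        g = igraph.Graph(n=len(uniq), edges=list(edges))
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights=list(edges.values()), resolution_parameter=resolution,
            seed=int(seed), n_iterations=-1)
        labels = np.asarray(part.membership, dtype=int)[inverse]
    return apply_size_floor(labels, min_cluster_size)


def niche_condition_composition(niche_labels: np.ndarray,
                                cellmap: CellMap) -> pd.DataFrame:
    """Per-sample fraction of cells in each niche.

    Fractions are computed over all of the sample's cells, so rows sum to
    ≤ 1; the unassigned fraction is reported in its own column.
    """
    df = cellmap.data.reset_index(drop=True).copy()
    df["niche"] = niche_labels
    tab = (df.groupby(["sample_id", "niche"]).size()
             .unstack(fill_value=0))
    frac = tab.div(tab.sum(axis=1), axis=0)
    frac.columns = ["unassigned" if c == UNASSIGNED_NICHE else f"niche_{c}"
                    for c in frac.columns]
    if "condition" in df.columns:
        cond = df.groupby("sample_id")["condition"].first()
        frac.insert(0, "condition", cond)
    return frac


def compare_conditions(proportions: pd.DataFrame, conditions: pd.Series,
                       ) -> pd.DataFrame:
    """Per-category two-sided unpaired t-tests on logit proportions with
    Holm–Šídák adjustment.

    ``proportions``: samples × categories (rows sum to ≤1); ``conditions``:
    sample → condition with exactly two levels and ≥2 samples each.  Zeros
    are replaced by half the minimum positive value observed for that
    category before the logit.  Categories constant across both conditions
    get p = 1.
    """
    levels = pd.unique(conditions)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {list(levels)}")
    g1 = proportions.loc[conditions[conditions == levels[0]].index]
    g2 = proportions.loc[conditions[conditions == levels[1]].index]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >=2 samples per condition")
    rows = []
    for cat in proportions.columns:
        a, b = g1[cat].to_numpy(float), g2[cat].to_numpy(float)
        pooled = np.concatenate([a, b])
        pos = pooled[pooled > 0]
        if len(pos) == 0 or np.ptp(pooled) == 0:
            rows.append((cat, np.nan, 1.0))
            continue
        repl = pos.min() / 2
        a = np.where(a > 0, a, repl)
        b = np.where(b > 0, b, repl)
        la, lb = logit(np.clip(a, None, 1 - 1e-12)), logit(np.clip(b, None, 1 - 1e-12))
        if np.ptp(np.concatenate([la, lb])) == 0:
            rows.append((cat, np.nan, 1.0))
            continue
        t, p = ttest_ind(la, lb)
        rows.append((cat, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["category", "t", "p_raw"]).set_index("category")
    # clip away exact 1.0 (constant categories): keeps the step-down finite
    out["p_adj"] = multipletests(np.clip(out["p_raw"].to_numpy(), 0, 1 - 1e-16),
                                 method="holm-sidak")[1].round(15)
    return out
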