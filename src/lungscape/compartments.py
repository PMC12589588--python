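"""Cell-type proportions in histological compartments and the associated
statistical battery.

Compartment membership is point-in-polygon against the annotated
compartment outlines (first matching polygon in file order wins on
overlap).  Proportions are computed against ALL cells of the compartment,
unannotated ("nan") cells included in the denominator.  Group composition
differences use PERMANOVA on a Bray–Curtis (or Euclidean) distance matrix;
matched designs use the Friedman test with Dunn's post-hoc or the paired
Wilcoxon test, unmatched designs use Kruskal–Wallis.  Spot-deconvolution
outputs are converted to comparable cell counts by the top-10 × 10
cells-per-spot rule before cross-method correlation on a shared coarse
type vocabulary.
"""

from __future__ import annotations

import warnings
from itertools import combinations, permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io import CellMap, GeometryAnnotation

__all__ = ["compartment_proportions", "permanova", "friedman_dunn",
           "paired_wilcoxon", "kruskal_by_type", "nonparametric_battery",
           "visium_cell_estimates", "cross_method_correlation", "row_normalize"]


# ---------------------------------------------------------------------------
# proportions
# ---------------------------------------------------------------------------

def compartment_proportions(cellmap: CellMap, geometry: GeometryAnnotation,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(sample, compartment) cell-type proportions.

    A cell belongs to the first compartment polygon (file order) containing
    it; cells outside every polygon go to compartment "outside".  The
    proportion denominator is all cells of the compartment, so per-row
    proportions sum to 1 when "nan" is included as a category.  Returns
    (proportions with rows (sample_id, compartment_id), assignment table).
    """
    import shapely

    df = cellmap.data.reset_index(drop=True).copy()
    pts = shapely.points(df[["x", "y"]].to_numpy(float))
    comp = np.full(len(df), "outside", dtype=object)
    label = np.full(len(df), "outside", dtype=object)
    unclaimed = np.ones(len(df), dtype=bool)
    overlap_warned = False
    for cid, clabel, poly in geometry.compartments:
        inside = shapely.contains(poly, pts)
        if (inside & ~unclaimed).any() and not overlap_warned:
            warnings.warn("overlapping compartment polygons: first in file order wins")
            overlap_warned = True
        take = inside & unclaimed
        comp[take], label[take] = cid, clabel
        unclaimed &= ~take
    df["compartment"] = comp
    df["compartment_label"] = label

    tab = (df.groupby(["sample_id", "compartment", "type_label"]).size()
             .unstack(fill_value=0))
    empty = [cid for cid, _, _ in geometry.compartments
             if cid not in tab.index.get_level_values("compartment")]
    if empty:
        warnings.warn(f"empty compartments excluded: {empty}")
    prop = tab.div(tab.sum(axis=1), axis=0)
    return prop, df[["cell_id", "sample_id", "compartment", "compartment_label"]]


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f(D2: np.ndarray, groups: np.ndarray, uniq: np.ndarray) -> float:
    """Pseudo-F from a squared-distance matrix: among/within sums of
    squares, SS_total = Σ_{i<j} d²/n and SS_within = Σ_g Σ_{i<j∈g} d²/n_g."""
    n = len(groups)
    a = len(uniq)
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in uniq:
        idx = groups == g
        ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * idx.sum())
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(proportions: pd.DataFrame, grouping: pd.Series, *,
              distance: str = "bray-curtis", n_permutations: int = 999,
              seed: int = 0, method: str = "sampled") -> dict:
    """Permutational multivariate ANOVA on composition vectors.

    ``proportions``: samples × types; ``grouping``: sample → group (≥2
    groups, ≥2 samples each).  The pseudo-F compares among- to within-group
    sums of squares on the distance matrix; the p-value is the fraction of
    label permutations with F ≥ observed, using the (b+1)/(m+1) estimator
    so it can never be zero.  ``method="exact"`` (≤8 samples) enumerates
    every distinct label arrangement instead of sampling.
    """
    X = proportions.loc[grouping.index].to_numpy(float)
    groups = grouping.to_numpy()
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >=2 groups with >=2 samples each")
    if distance == "bray-curtis":
        d = pdist(X, metric="braycurtis")
    elif distance == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if not np.any(d > 0):
        raise ValueError("degenerate distance matrix (all zeros)")
    D2 = squareform(d) ** 2
    n = len(groups)

    f_obs = _pseudo_f(D2, groups, uniq)
    if method == "exact":
        if n > 8:
            raise ValueError("exact enumeration supported for <=8 samples")
        # exhaustive: every distinct arrangement of the label multiset
        arrangements = {tuple(groups[list(p)]) for p in iter_permutations(range(n))}
        f_null = np.array([_pseudo_f(D2, np.array(p, dtype=object), uniq)
                           for p in arrangements])
        p_val = float((f_null >= f_obs - 1e-12).mean())
        m = len(arrangements)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            f = _pseudo_f(D2, groups[rng.permutation(n)], uniq)
            if f >= f_obs - 1e-12:
                hits += 1
        p_val = (hits + 1) / (n_permutations + 1)
        m = n_permutations
    return {"pseudo_F": float(f_obs), "p": float(p_val),
            "n_permutations": m, "distance": distance, "seed": seed}


# ---------------------------------------------------------------------------
# non-parametric battery
# ---------------------------------------------------------------------------

def friedman_dunn(block_table: pd.DataFrame) -> dict:
    """Friedman test across treatments (columns) with donors/blocks as rows,
    followed by Dunn's pairwise post-hoc (rank-sum z tests with Šidák family
    adjustment).  Requires complete blocks; incomplete rows are dropped."""
    tab = block_table.dropna(axis=0)
    dropped = len(block_table) - len(tab)
    if len(tab) < 3:
        raise ValueError("Friedman test needs >=3 complete blocks")
    b, k = tab.shape
    if np.ptp(tab.to_numpy()) == 0:
        pairs = pd.DataFrame(
            [(a, c, 0.0, 1.0) for a, c in combinations(tab.columns, 2)],
            columns=["a", "b", "z", "p_adj"])
        return {"statistic": 0.0, "p": 1.0, "dropped_blocks": dropped,
                "posthoc": pairs}
    stat, p = stats.friedmanchisquare(*[tab[c] for c in tab.columns])
    ranks = tab.rank(axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * b))
    rows = []
    for a, c in combinations(tab.columns, 2):
        z = (mean_ranks[a] - mean_ranks[c]) / se
        praw = 2 * stats.norm.sf(abs(z))
        rows.append((a, c, float(z), float(praw)))
    pairs = pd.DataFrame(rows, columns=["a", "b", "z", "p_raw"])
    pairs["p_adj"] = multipletests(pairs["p_raw"], method="sidak")[1]
    return {"statistic": float(stat), "p": float(p), "dropped_blocks": dropped,
            "posthoc": pairs}


def paired_wilcoxon(block_table: pd.DataFrame) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank test for every column pair (matched by
    block); identical pairs get p = 1."""
    tab = block_table.dropna(axis=0)
    rows = []
    for a, c in combinations(tab.columns, 2):
        diff = tab[a] - tab[c]
        if np.ptp(diff) == 0 and (diff == 0).all():
            rows.append((a, c, np.nan, 1.0))
            continue
        stat, p = stats.wilcoxon(tab[a], tab[c])
        rows.append((a, c, float(stat), float(p)))
    return pd.DataFrame(rows, columns=["a", "b", "statistic", "p"])


def kruskal_by_type(values: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Kruskal–Wallis test per column across unmatched groups."""
    rows = []
    for col in values.columns:
        samples = [values.loc[grouping[grouping == g].index, col].dropna()
                   for g in pd.unique(grouping)]
        samples = [s for s in samples if len(s)]
        flat = np.concatenate([np.asarray(s, float) for s in samples])
        if len(samples) < 2 or np.ptp(flat) == 0:
            rows.append((col, np.nan, 1.0))
            continue
        stat, p = stats.kruskal(*samples)
        rows.append((col, float(stat), float(p)))
    return pd.DataFrame(rows, columns=["category", "statistic", "p"])


def nonparametric_battery(proportions: pd.DataFrame, design: str, *,
                          grouping: pd.Series | None = None) -> dict:
    """Dispatch the appropriate non-parametric test battery.

    ``design="matched"``: ``proportions`` is blocks × compartments for one
    cell type; runs Friedman + Dunn and the paired Wilcoxon pairs.
    ``design="unmatched"``: ``proportions`` is samples × cell types with
    ``grouping`` sample → compartment; runs Kruskal–Wallis per type.
    """
    if design == "matched":
        return {"friedman": friedman_dunn(proportions),
                "wilcoxon": paired_wilcoxon(proportions)}
    if design == "unmatched":
        if grouping is None:
            raise ValueError("unmatched design requires a grouping")
        return {"kruskal": kruskal_by_type(proportions, grouping)}
    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# cross-method comparison
# ---------------------------------------------------------------------------

def visium_cell_estimates(weights: pd.DataFrame, *, top_n: int = 10,
                          cells_per_spot: int = 10) -> pd.DataFrame:
    """Convert per-spot deconvolution weights into estimated cell counts.

    ``weights``: spots × types, non-negative.  Per spot the ``top_n``
    largest weights are kept (ties at the cutoff break by type name;
    spots with fewer nonzero weights keep all of them, no padding) and
    multiplied by ``cells_per_spot``.  Returns a table with per-type
    estimated counts, the region total (n_spots × cells_per_spot) and
    proportions.
    """
    W = weights.copy().astype(float)
    if (W.to_numpy() < 0).any():
        raise ValueError("negative deconvolution weight")
    est = pd.Series(0.0, index=W.columns)
    for _, row in W.iterrows():
        nz = row[row > 0]
        # sort by weight desc then type name asc for a deterministic cutoff
        ordered = nz.sort_index().sort_values(ascending=False, kind="stable")
        kept = ordered.iloc[:top_n]
        est[kept.index] += kept * cells_per_spot
    total = len(W) * cells_per_spot
    return pd.DataFrame({"estimated_cells": est,
                         "proportion": est / total,
                         "region_total": total})


def cross_method_correlation(method_vectors: dict[str, pd.Series],
                             grouping: dict[str, str] | None = None,
                             ) -> pd.DataFrame:
    """Pairwise Pearson/Spearman correlation of per-type proportion vectors
    between methods.

    Fine labels are regrouped to the shared coarse vocabulary first when a
    ``grouping`` is given (coarse proportions are summed); types missing
    from one method are filled with 0.
    """
    coarse = {}
    for method, vec in method_vectors.items():
        v = vec.astype(float)
        if grouping is not None:
            v = v.groupby(lambda t: grouping.get(t, t)).sum()
        coarse[method] = v
    all_types = sorted(set().union(*(set(v.index) for v in coarse.values())))
    aligned = {m: v.reindex(all_types).fillna(0.0) for m, v in coarse.items()}
    rows = []
    for a, b in combinations(sorted(aligned), 2):
        r, _ = stats.pearsonr(aligned[a], aligned[b])
        rho, _ = stats.spearmanr(aligned[a], aligned[b])
        rows.append((a, b, float(r), float(rho)))
    return pd.DataFrame(rows, columns=["method_a", "method_b", "pearson", "spearman"])


def row_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its sum (all-zero rows are excluded with a
    warning), so rows sum to 1."""
    t = table.astype(float)
    if (t.to_numpy() < 0).any():
        raise ValueError("negative entries")
    sums = t.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"all-zero rows excluded: {list(t.index[zero])}")
        t = t.loc[~zero]
        sums = sums[~zero]
    return t.div(sums, axis=0)
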