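"""Baso-luminal axis quantification and rare-cell densities.

Airway epithelial transcripts/cells are positioned along the axis from the
basal membrane to the lumen: the raw distance is the minimum Euclidean
distance from a point to the traced basal-membrane polyline, normalized per
airway by the maximum observed distance, so every airway's points span
[0, 1] regardless of epithelial thickness.  Distances are binned into 10
equal-width groups to build per-gene profiles; a gene-selection filter
(expression floor per sample, low between-donor variance of the mean
distance, sufficient between-layer variability of the bin profile) picks
the genes whose layering is consistent across donors, which are then
compared by one-way ANOVA on donor-level means followed by Tukey HSD.

Rare-cell abundance is normalized per millimetre of basal-membrane length,
a thickness-independent regional measure; regions with less than 2 mm of
membrane are too short for a stable rate and are flagged ineligible.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString
from scipy import stats

__all__ = ["relative_depth", "bin_profile", "select_layer_genes",
           "layer_difference_test", "rare_density", "polyline_length",
           "RARE_CELL_SURVEY"]

#: Reference tally of manually annotated rare epithelial cells across four
#: donors (per-subtype counts and their total), used as a bookkeeping check.
RARE_CELL_SURVEY = {
    "ionocyte": 41,
    "tuft-like": 27,       # 24 tuft + 3 rare tuft-like
    "NE-GHRL": 9,
    "NE-PCSK1N": 32,
    "NE-ASCL1": 40,
    "NE-GRP": 31,
}
RARE_CELL_SURVEY_TOTAL = 180


def polyline_length(vertices: np.ndarray) -> float:
    """Length of a polyline in µm (sum of segment lengths)."""
    v = np.asarray(vertices, dtype=float)
    return float(np.hypot(*np.diff(v, axis=0).T).sum())


def relative_depth(points: np.ndarray, basal_curves: dict[str, np.ndarray],
                   airway_of: np.ndarray) -> pd.DataFrame:
    """Relative distance of each point from its airway's basal membrane.

    ``points``: (n, 2) µm; ``basal_curves``: airway_id → polyline vertices;
    ``airway_of``: airway id per point.  Raw distance is the minimum
    distance to the polyline's segments; normalization by the maximum raw
    distance is independent per airway, so membrane points map to 0 and the
    farthest point of each airway to 1.
    """
    points = np.asarray(points, dtype=float)
    airway_of = np.asarray(airway_of)
    raw = np.full(len(points), np.nan)
    rel = np.full(len(points), np.nan)
    for aid, verts in basal_curves.items():
        mask = airway_of == aid
        if not mask.any():
            continue
        line = LineString(np.asarray(verts, dtype=float))
        d = shapely.distance(shapely.points(points[mask]), line)
        raw[mask] = d
        dmax = d.max()
        if mask.sum() == 1 or dmax == 0:
            warnings.warn(f"airway {aid}: degenerate normalization, depth set to 0")
            rel[mask] = 0.0
        else:
            rel[mask] = d / dmax
    unknown = set(np.unique(airway_of)) - set(basal_curves)
    if unknown:
        raise ValueError(f"points assigned to airways with no basal curve: {sorted(unknown)}")
    return pd.DataFrame({"airway": airway_of, "raw_distance": raw,
                         "relative_distance": rel})


def bin_profile(relative_distances: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Fraction of transcripts per equal-width depth bin.

    Bins are half-open [i/n, (i+1)/n) with the last bin closed, so a
    relative distance of exactly 1 falls in the last bin.  Fractions sum
    to 1 for any non-empty input.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    d = np.asarray(relative_distances, dtype=float)
    if len(d) == 0:
        raise ValueError("no transcripts: bin profile undefined")
    idx = np.minimum((d * n_bins).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins) / len(d)


def select_layer_genes(depth_tables: dict[str, pd.DataFrame], *,
                       min_dots: int = 1500, max_donor_variance: float = 0.15,
                       min_layer_std: float = 0.05, n_bins: int = 10,
                       layer_stat: str = "bin_profile_sd",
                       ) -> tuple[list[str], pd.DataFrame]:
    """Select genes with consistent baso-luminal layering across donors.

    ``depth_tables``: donor → DataFrame with columns ``gene`` and
    ``relative_distance`` (one row per transcript).  A gene passes when
    (i) it has strictly more than ``min_dots`` transcripts in every donor,
    (ii) it is present in all donors, (iii) the variance across donors of
    its mean relative distance is below ``max_donor_variance``, and
    (iv) its pooled bin-fraction profile has standard deviation above
    ``min_layer_std`` (the flat-profile filter; the alternative reading —
    sd of per-bin mean distances — is available via ``layer_stat``).
    Returns the passing gene list plus the full per-gene statistics table.
    """
    if len(depth_tables) < 2:
        raise ValueError("need at least 2 donors")
    donors = sorted(depth_tables)
    all_genes = sorted(set().union(*(set(t["gene"]) for t in depth_tables.values())))
    rows = []
    for gene in all_genes:
        per_donor_counts, per_donor_means, pooled = {}, {}, []
        for donor in donors:
            t = depth_tables[donor]
            d = t.loc[t["gene"] == gene, "relative_distance"].to_numpy(float)
            per_donor_counts[donor] = len(d)
            per_donor_means[donor] = d.mean() if len(d) else np.nan
            pooled.append(d)
        pooled = np.concatenate(pooled)
        in_all = all(per_donor_counts[d] > 0 for d in donors)
        enough = all(per_donor_counts[d] > min_dots for d in donors)
        means = np.array([per_donor_means[d] for d in donors], dtype=float)
        donor_var = np.nanvar(means, ddof=1) if in_all else np.nan
        if len(pooled):
            prof = bin_profile(pooled, n_bins)
            if layer_stat == "bin_profile_sd":
                layer_sd = float(prof.std(ddof=0))
            elif layer_stat == "bin_mean_distance_sd":
                idx = np.minimum((pooled * n_bins).astype(int), n_bins - 1)
                bin_means = [pooled[idx == b].mean() for b in range(n_bins)
                             if (idx == b).any()]
                layer_sd = float(np.std(bin_means, ddof=0))
            else:
                raise ValueError(f"unknown layer_stat {layer_stat!r}")
        else:
            layer_sd = np.nan
        passes = (enough and in_all
                  and np.isfinite(donor_var) and donor_var < max_donor_variance
                  and np.isfinite(layer_sd) and layer_sd > min_layer_std)
        rows.append({"gene": gene, "in_all_donors": in_all,
                     "min_donor_dots": min(per_donor_counts.values()),
                     "donor_variance": donor_var, "layer_sd": layer_sd,
                     "passes": passes,
                     **{f"mean_distance_{d}": per_donor_means[d] for d in donors}})
    table = pd.DataFrame(rows).set_index("gene")
    return table.index[table["passes"]].tolist(), table


def layer_difference_test(donor_means: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare genes' axis positions: one-way ANOVA on donor-level mean
    distances (gene as factor, donors as replicates) followed by Tukey HSD.

    ``donor_means``: genes × donors table of mean relative distances; genes
    with fewer than 2 donor values are excluded with a warning.  Returns
    (ANOVA summary, pairwise Tukey table).
    """
    groups, names = [], []
    for gene, row in donor_means.iterrows():
        vals = row.dropna().to_numpy(float)
        if len(vals) < 2:
            warnings.warn(f"gene {gene}: single donor value, excluded")
            continue
        groups.append(vals)
        names.append(gene)
    if len(groups) < 2:
        raise ValueError("need at least 2 genes with >=2 donor values")
    if np.ptp(np.concatenate(groups)) == 0:
        anova = pd.DataFrame({"F": [np.nan], "p": [1.0]})
        pairs = [(a, b, 0.0, 1.0) for i, a in enumerate(names) for b in names[i + 1:]]
        return anova, pd.DataFrame(pairs, columns=["gene_a", "gene_b", "diff", "p_adj"])
    F, p = stats.f_oneway(*groups)
    anova = pd.DataFrame({"F": [float(F)], "p": [float(p)]})
    tk = stats.tukey_hsd(*groups)
    pairs = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            pairs.append((a, names[j],
                          float(np.mean(groups[i]) - np.mean(groups[j])),
                          float(tk.pvalue[i, j])))
    return anova, pd.DataFrame(pairs, columns=["gene_a", "gene_b", "diff", "p_adj"])


def rare_density(rare_counts: pd.Series, membrane_lengths_um: pd.Series,
                 epithelial_counts: pd.Series, *,
                 min_length_mm: float = 2.0) -> pd.DataFrame:
    """Rare-cell abundance per region: cells per mm of basal membrane and
    percentage of airway epithelial cells.

    Regions whose membrane is shorter than ``min_length_mm`` are flagged
    ineligible (their values are still reported).
    """
    regions = membrane_lengths_um.index
    lengths_mm = membrane_lengths_um.astype(float) / 1000.0
    if (lengths_mm <= 0).any():
        raise ValueError("zero-length basal membrane")
    counts = rare_counts.reindex(regions).fillna(0).astype(float)
    epi = epithelial_counts.reindex(regions).astype(float)
    return pd.DataFrame({
        "rare_cells": counts,
        "membrane_mm": lengths_mm,
        "cells_per_mm": counts / lengths_mm,
        "percent_of_epithelial": 100.0 * counts / epi,
        "eligible": lengths_mm >= min_length_mm,
    })
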