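"""Synthetic lung-like tissue with known ground truth.

The generator emulates the tissue structures the downstream analyses
operate on, at a desk scale:

* an airway cross-section — a circular lumen wrapped by an epithelial band
  whose cell types occupy preferred baso-luminal depths (basal cells at the
  basal membrane, ciliated cells at the lumen), with the basal membrane
  emitted as a polyline;
* alveolar parenchyma — a rectangular field of mixed alveolar epithelial,
  stromal, endothelial and immune types;
* planted niches — polygonal regions whose cells are drawn from a distinct
  type mixture, giving the niche analyses an exact truth;
* a condition contrast — per-type multiplicative abundance shifts applied
  to "COPD" samples (e.g. an AT0 expansion).

Cells are placed by a hard-core point process (minimum separation = one
nucleus diameter).  Per-cell transcript counts are negative binomial around
the type's expression profile (Poisson in the infinite-dispersion limit),
scattered uniformly inside the nuclear disk so a 2 µm mask expansion
recovers them.  Background transcripts arrive as a
spatial Poisson process with uniformly random gene labels.

Every cell carries its true type, niche and relative baso-luminal depth,
so parameter-recovery tests have an exact reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .io import (CellMap, Codebook, GeometryAnnotation, NucleiSet,
                 SpotIntensitySeries, TranscriptTable)

__all__ = ["SynthConfig", "default_profiles", "default_config",
           "generate_tissue", "generate_spot_intensities",
           "generate_condition_pair"]


def default_profiles() -> pd.DataFrame:
    """Type × gene mean transcript counts: two strong markers per type on a
    low uniform off-target floor, matching the 1–20 dots/cell range typical
    of targeted in-situ panels."""
    types = {
        "basal":        ["KRT5", "KRT15"],
        "suprabasal":   ["SERPINB3", "HSPB1"],
        "secretory":    ["SCGB1A1", "BPIFB1"],
        "ciliated":     ["FOXJ1", "CAPS"],
        "AT1":          ["AGER", "PDPN"],
        "AT2":          ["SFTPC", "NAPSA"],
        "AT0":          ["SCGB3A2", "LCN2"],
        "fibroblast":   ["COL1A1", "RGCC"],
        "endothelial":  ["CLDN5", "PECAM1"],
        "immune":       ["PTPRC", "CD3E"],
    }
    genes = [g for gs in types.values() for g in gs]
    prof = pd.DataFrame(0.2, index=list(types), columns=genes)
    for t, gs in types.items():
        for g in gs:
            prof.loc[t, g] = 12.0
    # AT0 co-expresses the AT2 program at reduced level (intermediate state)
    prof.loc["AT0", "SFTPC"] = 5.0
    prof.loc["AT0", "NAPSA"] = 5.0
    return prof


@dataclass
class SynthConfig:
    """Parameters of the synthetic tissue; defaults give a single airway
    plus an alveolar field of roughly 1.5k cells."""

    # geometry (µm)
    lumen_radius: float = 150.0
    epithelial_thickness: float = 50.0
    alveolar_extent: tuple[float, float] = (800.0, 800.0)
    alveolar_offset: float = 80.0        # gap between airway and field
    nucleus_radius: float = 4.0
    min_separation: float = 8.0          # hard-core distance (1 nucleus diameter)
    # populations
    n_epithelial: int = 600
    n_alveolar: int = 900
    epithelial_mixture: dict = field(default_factory=lambda: {
        "basal": 0.25, "suprabasal": 0.30, "secretory": 0.25, "ciliated": 0.20})
    alveolar_mixture: dict = field(default_factory=lambda: {
        "AT1": 0.15, "AT2": 0.20, "AT0": 0.05, "fibroblast": 0.25,
        "endothelial": 0.20, "immune": 0.15})
    # relative baso-luminal depth preference per epithelial type: (mean, sd)
    layer_preferences: dict = field(default_factory=lambda: {
        "basal": (0.12, 0.08), "suprabasal": (0.38, 0.10),
        "secretory": (0.65, 0.10), "ciliated": (0.88, 0.08)})
    # expression
    type_profiles: pd.DataFrame = field(default_factory=default_profiles)
    dispersion: float = 10.0             # NB size; inf -> Poisson
    # transcripts scatter uniformly in a disk of this radius around the
    # nucleus centre; kept <= min_separation/2 so a transcript is always
    # nearer its own nucleus than any neighbor's
    transcript_scatter: float = 4.0
    background_rate: float = 0.0         # transcripts per µm²
    # planted niches: list of (niche_id, Polygon, mixture dict) in the field
    niche_plan: list = field(default_factory=list)
    # condition shift: type -> abundance multiplier applied to "COPD" samples
    condition_effect: dict = field(default_factory=lambda: {"AT0": 4.0})

    def __post_init__(self) -> None:
        for name, mix in (("epithelial_mixture", self.epithelial_mixture),
                          ("alveolar_mixture", self.alveolar_mixture)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(mix.values())})")
        for nid, poly, mix in self.niche_plan:
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"niche {nid} mixture must sum to 1")
        if any(m <= 0 for m in self.condition_effect.values()):
            raise ValueError("condition_effect multipliers must be > 0")
        if (self.type_profiles.to_numpy() < 0).any():
            raise ValueError("type_profiles must be non-negative")


def default_config(**overrides) -> SynthConfig:
    return SynthConfig(**overrides)


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

class _HardCore:
    """Grid-backed hard-core acceptance test (min distance between points)."""

    def __init__(self, min_sep: float):
        self.min_sep = min_sep
        self.cell = max(min_sep, 1e-6)
        self.grid: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def try_add(self, x: float, y: float) -> bool:
        gx, gy = int(np.floor(x / self.cell)), int(np.floor(y / self.cell))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for (px, py) in self.grid.get((gx + dx, gy + dy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < self.min_sep ** 2:
                        return False
        self.grid.setdefault((gx, gy), []).append((x, y))
        return True


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if not np.isfinite(dispersion):
        return rng.poisson(mean)
    # NB as Gamma-Poisson mixture
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------

def generate_tissue(config: SynthConfig, seed: int, *, sample_id: str = "synth_0",
                    condition: str = "healthy", region: str = "distal",
                    ) -> tuple[CellMap, TranscriptTable, NucleiSet, GeometryAnnotation]:
    """Generate one synthetic sample with truth labels.

    Returns the cell map (with ``true_type``/``true_niche``/``true_depth``
    columns), the transcript table, the nuclei centroid set and the
    geometry (basal polyline + airway/alveolar compartment polygons).
    """
    rng = np.random.default_rng(seed)
    r_out = config.lumen_radius + config.epithelial_thickness
    hc = _HardCore(config.min_separation)

    apply_effect = condition == "COPD"

    def adjusted(mix: dict) -> tuple[list[str], np.ndarray]:
        names = sorted(mix)
        w = np.array([mix[t] for t in names], dtype=float)
        if apply_effect:
            for i, t in enumerate(names):
                w[i] *= config.condition_effect.get(t, 1.0)
        return names, w / w.sum()

    cells = []   # (x, y, true_type, true_niche, true_depth)

    # --- airway epithelium -------------------------------------------------
    ep_names, ep_w = adjusted(config.epithelial_mixture)
    placed = 0
    attempts = 0
    while placed < config.n_epithelial and attempts < config.n_epithelial * 200:
        attempts += 1
        t = ep_names[rng.choice(len(ep_names), p=ep_w)]
        mu, sd = config.layer_preferences[t]
        depth = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
        # depth 0 at the basal membrane (outer boundary), 1 at the lumen
        r = r_out - depth * config.epithelial_thickness
        theta = rng.uniform(0, 2 * np.pi)
        x, y = r * np.cos(theta), r * np.sin(theta)
        if hc.try_add(x, y):
            cells.append((x, y, t, "", depth))
            placed += 1

    # --- alveolar field ----------------------------------------------------
    alv_names, alv_w = adjusted(config.alveolar_mixture)
    x0 = r_out + config.alveolar_offset
    wx, wy = config.alveolar_extent
    niche_polys = [(nid, poly, adjusted(mix)) for nid, poly, mix in config.niche_plan]
    placed = 0
    attempts = 0
    while placed < config.n_alveolar and attempts < config.n_alveolar * 200:
        attempts += 1
        x = rng.uniform(x0, x0 + wx)
        y = rng.uniform(-wy / 2, wy / 2)
        if not hc.try_add(x, y):
            continue
        niche = ""
        names, w = alv_names, alv_w
        for nid, poly, (nnames, nw) in niche_polys:
            if poly.contains(Point(x, y)):
                niche, names, w = nid, nnames, nw
                break
        t = names[rng.choice(len(names), p=w)]
        cells.append((x, y, t, niche, np.nan))
        placed += 1

    cell_df = pd.DataFrame(cells, columns=["x", "y", "true_type", "true_niche",
                                           "true_depth"])
    cell_df.insert(0, "cell_id", np.arange(1, len(cell_df) + 1))
    cell_df["type_label"] = cell_df["true_type"]
    cell_df["sample_id"] = sample_id
    cell_df["condition"] = condition
    cell_df["region"] = region

    # --- transcripts -------------------------------------------------------
    prof = config.type_profiles
    genes = prof.columns.to_numpy()
    tx_rows = []
    for _, c in cell_df.iterrows():
        counts = _draw_counts(rng, prof.loc[c["true_type"]].to_numpy(),
                              config.dispersion)
        n_tx = int(counts.sum())
        if n_tx == 0:
            continue
        gene_list = np.repeat(genes, counts)
        rr = config.transcript_scatter * np.sqrt(rng.uniform(size=n_tx))
        th = rng.uniform(0, 2 * np.pi, size=n_tx)
        tx_rows.append(pd.DataFrame({
            "x": c["x"] + rr * np.cos(th), "y": c["y"] + rr * np.sin(th),
            "gene": gene_list, "true_cell": int(c["cell_id"])}))
    # background transcripts over the full footprint
    if config.background_rate > 0:
        area = np.pi * r_out ** 2 + wx * wy
        n_bg = rng.poisson(config.background_rate * area)
        if n_bg:
            # rejection-free: half in airway disk, half in field, area-weighted
            in_disk = rng.uniform(size=n_bg) < (np.pi * r_out ** 2) / area
            xs, ys = np.empty(n_bg), np.empty(n_bg)
            nd = int(in_disk.sum())
            rd = r_out * np.sqrt(rng.uniform(size=nd))
            td = rng.uniform(0, 2 * np.pi, size=nd)
            xs[in_disk], ys[in_disk] = rd * np.cos(td), rd * np.sin(td)
            nf = n_bg - nd
            xs[~in_disk] = rng.uniform(x0, x0 + wx, size=nf)
            ys[~in_disk] = rng.uniform(-wy / 2, wy / 2, size=nf)
            tx_rows.append(pd.DataFrame({
                "x": xs, "y": ys,
                "gene": rng.choice(genes, size=n_bg), "true_cell": -1}))
    tx = (pd.concat(tx_rows, ignore_index=True) if tx_rows
          else pd.DataFrame(columns=["x", "y", "gene", "true_cell"]))
    tx["sample_id"] = sample_id
    tx["region"] = region

    nuclei = NucleiSet(centroids=pd.DataFrame({
        "nucleus_id": cell_df["cell_id"],
        "x": cell_df["x"], "y": cell_df["y"],
        "radius": config.nucleus_radius}))

    # basal membrane: polyline along the epithelium's outer boundary
    th = np.linspace(0, 2 * np.pi, 181)
    basal = np.column_stack([r_out * np.cos(th), r_out * np.sin(th)])
    airway_poly = Polygon(np.column_stack([(r_out + 20) * np.cos(th[:-1]),
                                           (r_out + 20) * np.sin(th[:-1])]))
    field_poly = Polygon([(x0, -wy / 2), (x0 + wx, -wy / 2),
                          (x0 + wx, wy / 2), (x0, wy / 2)])
    geom = GeometryAnnotation(
        basal_curves=[("airway_1", basal)],
        compartments=[("airway_1", "airway", airway_poly),
                      ("alveolar_1", "alveolar", field_poly)])

    return CellMap(cell_df), TranscriptTable(tx), nuclei, geom


def generate_spot_intensities(codebook: Codebook, n_spots: int, noise_sd: float,
                              seed: int) -> tuple[SpotIntensitySeries, np.ndarray]:
    """Simulate decoding input: per-round one-hot intensities for a random
    gene from the codebook plus Gaussian noise truncated at zero.  Returns
    the series and the true gene per spot."""
    if len(codebook) == 0:
        raise ValueError("empty codebook")
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = np.array(sorted(codebook.entries))
    truth = rng.choice(genes, size=n_spots)
    inten = np.zeros((n_spots, codebook.rounds, codebook.channels))
    for i, g in enumerate(truth):
        for r, c in enumerate(codebook.entries[g]):
            inten[i, r, c] = 1.0
    if noise_sd > 0:
        inten = np.clip(inten + rng.normal(0, noise_sd, size=inten.shape), 0, None)
    xy = rng.uniform(0, 1000, size=(n_spots, 2))
    return SpotIntensitySeries(np.arange(n_spots), xy, inten), truth


def generate_condition_pair(config: SynthConfig, n_samples_per_condition: int,
                            seed: int) -> list[tuple[CellMap, TranscriptTable,
                                                     NucleiSet, GeometryAnnotation]]:
    """Generate matched healthy / "COPD" sample sets.

    COPD samples apply ``config.condition_effect`` to type abundances before
    placement; per-sample seeds derive deterministically from the master
    seed."""
    if n_samples_per_condition < 1:
        raise ValueError("n_samples_per_condition must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        2 * n_samples_per_condition) % (2 ** 31)
    out = []
    i = 0
    for condition in ("healthy", "COPD"):
        for s in range(n_samples_per_condition):
            out.append(generate_tissue(
                config, int(child_seeds[i]),
                sample_id=f"{condition}_{s + 1}", condition=condition))
            i += 1
    return out
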