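"""Domain containers and file readers/writers shared by all pipeline stages.

Coordinates are real-valued micrometres in a per-sample frame, with y
increasing downward (raster convention).  Label images are converted to
micrometres through their ``pixel_size``.  MatrixMarket indices are 1-based
on disk and 0-based in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "TranscriptTable",
    "Codebook",
    "SpotIntensitySeries",
    "NucleiSet",
    "CellByGene",
    "CellMap",
    "GeometryAnnotation",
    "read_transcripts",
    "write_transcripts",
    "read_cell_by_gene",
    "write_cell_by_gene",
    "read_codebook",
    "read_spot_intensities",
    "write_spot_intensities",
    "read_nuclei",
    "read_geometry",
    "write_geometry",
    "read_cellmap",
    "write_cellmap",
]

REGIONS = ("trachea", "proximal", "distal", "unknown")
COMPARTMENT_LABELS = ("SMG", "airway", "alveolar", "vein", "artery", "cartilage")


class FormatError(ValueError):
    """Raised when an input file violates the documented schema."""


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

@dataclass
class TranscriptTable:
    """Decoded transcript positions with gene labels.

    ``data`` holds one row per transcript with columns ``x``, ``y`` (µm),
    ``gene`` and optionally ``quality`` (in (0, 1]), ``cell_id`` (-1 means
    unassigned), ``sample_id`` and ``region``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("x", "y", "gene"):
            if col not in df.columns:
                raise FormatError(f"transcript table missing required column {col!r}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise FormatError(f"non-finite coordinate at row {bad}")
        if (df["gene"].astype(str).str.len() == 0).any():
            raise FormatError("empty gene label")
        if "quality" in df.columns:
            q = df["quality"].dropna()
            if len(q) and ((q <= 0) | (q > 1)).any():
                raise FormatError("quality values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def assigned(self) -> pd.DataFrame:
        """Rows carrying a cell assignment."""
        if "cell_id" not in self.data.columns:
            return self.data.iloc[0:0]
        return self.data[self.data["cell_id"] >= 0]


def read_transcripts(path: str | Path, dialect: Mapping[str, str] | None = None) -> TranscriptTable:
    """Read a transcript CSV/TSV.  ``dialect`` maps canonical column names
    (x, y, gene, ...) to the names used in the file."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    for col in ("x", "y", "gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise FormatError(f"{path}: non-numeric {col} at line {line}")
        df[col] = coerced
    return TranscriptTable(df)


def write_transcripts(table: TranscriptTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    table.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# codebook + spot intensities
# ---------------------------------------------------------------------------

@dataclass
class Codebook:
    """Gene → barcode map, each barcode a length-R tuple of channel indices."""

    rounds: int
    channels: int
    entries: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise FormatError("codebook needs at least one round")
        if self.channels < 2:
            raise FormatError("codebook needs at least two channels")
        seen: dict[tuple[int, ...], str] = {}
        for gene, bc in self.entries.items():
            bc = tuple(int(c) for c in bc)
            if len(bc) != self.rounds:
                raise FormatError(f"barcode for {gene} has length {len(bc)}, expected {self.rounds}")
            if any(c < 0 or c >= self.channels for c in bc):
                raise FormatError(f"barcode for {gene} uses a channel outside [0, {self.channels})")
            if bc in seen:
                raise FormatError(f"barcode {bc} shared by {seen[bc]} and {gene}")
            seen[bc] = gene
            self.entries[gene] = bc

    def lookup(self) -> dict[tuple[int, ...], str]:
        return {bc: gene for gene, bc in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)


def read_codebook(path: str | Path) -> Codebook:
    """Read a codebook from JSON ({rounds, channels, entries}) or CSV
    (columns gene, r0..r{R-1})."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        return Codebook(int(obj["rounds"]), int(obj["channels"]),
                        {g: tuple(bc) for g, bc in obj["entries"].items()})
    df = pd.read_csv(path)
    if "gene" not in df.columns:
        raise FormatError(f"{path}: missing required column 'gene'")
    round_cols = [c for c in df.columns if c.startswith("r") and c[1:].isdigit()]
    round_cols.sort(key=lambda c: int(c[1:]))
    if not round_cols:
        raise FormatError(f"{path}: no round columns (r0, r1, ...)")
    entries = {row["gene"]: tuple(int(row[c]) for c in round_cols) for _, row in df.iterrows()}
    channels = int(max(max(bc) for bc in entries.values())) + 1
    return Codebook(len(round_cols), max(channels, 2), entries)


@dataclass
class SpotIntensitySeries:
    """Per-spot, per-round, per-channel fluorescence intensities."""

    spot_ids: np.ndarray          # (n,)
    xy: np.ndarray                # (n, 2) µm
    intensity: np.ndarray         # (n, R, C) non-negative

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids)
        self.xy = np.asarray(self.xy, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise FormatError("intensity must be (spots, rounds, channels)")
        if (self.intensity < 0).any():
            raise FormatError("negative intensity")

    def __len__(self) -> int:
        return len(self.spot_ids)

    @property
    def rounds(self) -> int:
        return self.intensity.shape[1]

    @property
    def channels(self) -> int:
        return self.intensity.shape[2]


def read_spot_intensities(path: str | Path) -> SpotIntensitySeries:
    """Read the long-form CSV: spot_id,x,y,round,channel,intensity."""
    df = pd.read_csv(path)
    required = {"spot_id", "x", "y", "round", "channel", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    spot_ids = np.sort(df["spot_id"].unique())
    R = int(df["round"].max()) + 1
    C = int(df["channel"].max()) + 1
    idx = pd.Series(np.arange(len(spot_ids)), index=spot_ids)
    inten = np.zeros((len(spot_ids), R, C))
    inten[idx[df["spot_id"]].to_numpy(), df["round"], df["channel"]] = df["intensity"]
    xy = df.groupby("spot_id")[["x", "y"]].first().loc[spot_ids].to_numpy()
    return SpotIntensitySeries(spot_ids, xy, inten)


def write_spot_intensities(series: SpotIntensitySeries, path: str | Path) -> None:
    n, R, C = series.intensity.shape
    rec = {
        "spot_id": np.repeat(series.spot_ids, R * C),
        "x": np.repeat(series.xy[:, 0], R * C),
        "y": np.repeat(series.xy[:, 1], R * C),
        "round": np.tile(np.repeat(np.arange(R), C), n),
        "channel": np.tile(np.arange(C), n * R),
        "intensity": series.intensity.ravel(),
    }
    pd.DataFrame(rec).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------

@dataclass
class NucleiSet:
    """Segmented nuclei, as a label raster or as centroid disks.

    Exactly one of ``label_image`` (2-D integer array, background 0, with
    ``pixel_size`` µm/px) or ``centroids`` (DataFrame nucleus_id, x, y,
    radius in µm) is set.
    """

    label_image: np.ndarray | None = None
    pixel_size: float | None = None
    centroids: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.label_image is None) == (self.centroids is None):
            raise FormatError("provide exactly one of label_image or centroids")
        if self.label_image is not None:
            if self.pixel_size is None or self.pixel_size <= 0:
                raise FormatError("label image requires pixel_size > 0")
            self.label_image = np.asarray(self.label_image)
            if self.label_image.ndim != 2:
                raise FormatError("label image must be 2-D")
            if self.label_image.min() < 0:
                raise FormatError("negative label")
        else:
            df = self.centroids
            for col in ("nucleus_id", "x", "y", "radius"):
                if col not in df.columns:
                    raise FormatError(f"centroid table missing column {col!r}")
            if df["nucleus_id"].duplicated().any():
                raise FormatError("duplicate nucleus ids")
            if (df["nucleus_id"] <= 0).any():
                raise FormatError("nucleus ids must be > 0")
            if (df["radius"] <= 0).any():
                raise FormatError("nucleus radii must be > 0")

    @property
    def is_raster(self) -> bool:
        return self.label_image is not None

    def ids(self) -> np.ndarray:
        if self.is_raster:
            labels = np.unique(self.label_image)
            return labels[labels > 0]
        return np.sort(self.centroids["nucleus_id"].to_numpy())


def read_nuclei(path: str | Path, pixel_size: float | None = None) -> NucleiSet:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return NucleiSet(label_image=tifffile.imread(path), pixel_size=pixel_size)
    return NucleiSet(centroids=pd.read_csv(path))


# ---------------------------------------------------------------------------
# cell-by-gene
# ---------------------------------------------------------------------------

@dataclass
class CellByGene:
    """Sparse cells × genes count matrix with ordered id lists."""

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        self.gene_ids = np.asarray(self.gene_ids)
        self.counts = sp.csr_matrix(self.counts)
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell ids")
        if len(np.unique(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match id lists "
                f"({len(self.cell_ids)} cells, {len(self.gene_ids)} genes)")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def totals(self) -> np.ndarray:
        """Per-cell total counts."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of distinct genes with at least one count."""
        return np.diff(self.counts.indptr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.toarray(), index=self.cell_ids, columns=self.gene_ids)


def read_cell_by_gene(mtx_path: str | Path, cells_path: str | Path,
                      genes_path: str | Path) -> CellByGene:
    """Read a MatrixMarket coordinate matrix plus id lists; duplicate
    (cell, gene) triplets are summed."""
    mat = scipy.io.mmread(mtx_path)   # COO; mmread sums duplicates on tocsr
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].to_numpy()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy()
    if mat.shape != (len(cells), len(genes)):
        raise FormatError(
            f"{mtx_path}: header shape {mat.shape} does not match id lists "
            f"({len(cells)} cells, {len(genes)} genes)")
    csr = sp.csr_matrix(mat)
    csr.sum_duplicates()
    return CellByGene(cells, genes, csr)


def write_cell_by_gene(cbg: CellByGene, mtx_path: str | Path,
                       cells_path: str | Path, genes_path: str | Path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cbg.counts), field="integer")
    pd.Series(cbg.cell_ids).to_csv(cells_path, sep="\t", header=False, index=False)
    pd.Series(cbg.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# cell map
# ---------------------------------------------------------------------------

@dataclass
class CellMap:
    """Per-cell coordinates and annotations; the substrate of the spatial
    analyses.  Columns: cell_id, x, y, type_label, sample_id, condition,
    region, and optionally compartment plus truth columns from simulation."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("cell_id", "x", "y", "type_label", "sample_id"):
            if col not in df.columns:
                raise FormatError(f"cell map missing column {col!r}")
        dup = df.duplicated(subset=["sample_id", "cell_id"])
        if dup.any():
            raise FormatError("duplicate cell ids within a sample")

    def __len__(self) -> int:
        return len(self.data)

    def per_sample(self):
        return self.data.groupby("sample_id", sort=True)


def read_cellmap(path: str | Path) -> CellMap:
    return CellMap(pd.read_csv(path))


def write_cellmap(cm: CellMap, path: str | Path) -> None:
    cm.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class GeometryAnnotation:
    """Basal-membrane polylines and histological compartment polygons.

    ``basal_curves``: list of (airway_id, (n, 2) vertex array in µm).
    ``compartments``: list of (compartment_id, label, shapely Polygon).
    """

    basal_curves: list[tuple[str, np.ndarray]] = field(default_factory=list)
    compartments: list[tuple[str, str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        from shapely.geometry import Polygon

        curves = []
        for aid, verts in self.basal_curves:
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or len(np.unique(verts, axis=0)) < 2:
                raise FormatError(f"basal curve {aid} needs >=2 distinct vertices")
            curves.append((str(aid), verts))
        self.basal_curves = curves
        comps = []
        for cid, label, poly in self.compartments:
            if label not in COMPARTMENT_LABELS:
                raise FormatError(f"compartment label {label!r} not in {COMPARTMENT_LABELS}")
            if not isinstance(poly, Polygon):
                poly = Polygon(poly)
            if not poly.is_valid:
                raise FormatError(f"compartment {cid} polygon is not simple")
            comps.append((str(cid), label, poly))
        self.compartments = comps


def read_geometry(path: str | Path) -> GeometryAnnotation:
    """Read GeoJSON: LineString features with role=basal, Polygon features
    with role=compartment and a label property."""
    obj = json.loads(Path(path).read_text())
    curves, comps = [], []
    for i, feat in enumerate(obj.get("features", [])):
        props = feat.get("properties") or {}
        geom = feat["geometry"]
        role = props.get("role")
        if role == "basal":
            curves.append((props.get("airway_id", f"airway_{i}"),
                           np.asarray(geom["coordinates"], dtype=float)))
        elif role == "compartment":
            from shapely.geometry import shape

            comps.append((props.get("compartment_id", f"comp_{i}"),
                          props["label"], shape(geom)))
        else:
            raise FormatError(f"feature {i}: unknown role {role!r}")
    return GeometryAnnotation(curves, comps)


def write_geometry(geom: GeometryAnnotation, path: str | Path) -> None:
    from shapely.geometry import mapping

    feats = []
    for aid, verts in geom.basal_curves:
        feats.append({
            "type": "Feature",
            "properties": {"role": "basal", "airway_id": aid},
            "geometry": {"type": "LineString", "coordinates": np.asarray(verts).tolist()},
        })
    for cid, label, poly in geom.compartments:
        feats.append({
            "type": "Feature",
            "properties": {"role": "compartment", "compartment_id": cid, "label": label},
            "geometry": mapping(poly),
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
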