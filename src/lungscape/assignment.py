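"""Transcript-to-cell assignment and per-protocol QC.

Nuclear masks (label raster or centroid disks) are expanded by a fixed
radius (default 2 µm) without overlaps, transcripts falling inside an
expanded region inherit its cell id, and the assigned transcripts are
tabulated into a sparse cell-by-gene matrix.  Assignment is purely
geometric and deterministic; externally produced assignments (e.g. from a
probabilistic re-segmentation) can be passed straight to
:func:`build_matrix`.

QC protocols
------------
``hybiss``           drop cells with <3 distinct genes OR <5 total counts
``scrinshot``        drop cells with <25 total counts
``scrinshot_copd``   drop cells with <8 total counts
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .io import CellByGene, NucleiSet, TranscriptTable

__all__ = ["expand_nuclei", "assign_transcripts", "build_matrix", "qc_filter", "QCReport"]


def expand_nuclei(nuclei: NucleiSet, radius_um: float) -> NucleiSet:
    """Expand every nucleus by ``radius_um`` without overlap.

    Raster form: morphological dilation where contested pixels go to the
    nearest original label.  Centroid form: effective radius grows by
    ``radius_um``.
    """
    if radius_um < 0:
        raise ValueError("expansion radius must be >= 0")
    if nuclei.is_raster:
        from skimage.segmentation import expand_labels

        dist_px = radius_um / nuclei.pixel_size
        expanded = expand_labels(nuclei.label_image, distance=dist_px)
        return NucleiSet(label_image=expanded, pixel_size=nuclei.pixel_size)
    cents = nuclei.centroids.copy()
    cents["radius"] = cents["radius"] + radius_um
    return NucleiSet(centroids=cents)


def assign_transcripts(transcripts: TranscriptTable, nuclei: NucleiSet) -> TranscriptTable:
    """Attach ``cell_id`` to each transcript inside an expanded cell region.

    Transcripts outside every region get cell_id -1.  In the centroid form a
    point inside several overlapping disks goes to the disk whose centre is
    nearest; exact boundary/distance ties go to the lower cell id.
    """
    df = transcripts.data.copy()
    n_nuclei = (0 if nuclei.is_raster and nuclei.label_image.max() == 0
                else len(nuclei.ids()))
    if n_nuclei == 0:
        warnings.warn("empty nuclei set: all transcripts left unassigned")
        df["cell_id"] = -1
        return TranscriptTable(df)

    xy = df[["x", "y"]].to_numpy(dtype=float)
    if nuclei.is_raster:
        px = np.floor(xy / nuclei.pixel_size).astype(int)
        h, w = nuclei.label_image.shape
        inside = (px[:, 0] >= 0) & (px[:, 0] < w) & (px[:, 1] >= 0) & (px[:, 1] < h)
        cell = np.full(len(df), -1, dtype=int)
        # raster convention: x is the column, y the row
        cell[inside] = nuclei.label_image[px[inside, 1], px[inside, 0]]
        cell[cell == 0] = -1
    else:
        cents = nuclei.centroids.sort_values("nucleus_id")  # lower id wins ties
        centers = cents[["x", "y"]].to_numpy(dtype=float)
        radii = cents["radius"].to_numpy(dtype=float)
        ids = cents["nucleus_id"].to_numpy()
        tree = cKDTree(centers)
        rmax = radii.max()
        cell = np.full(len(df), -1, dtype=int)
        # all centroids within the largest radius are candidates
        neighbors = tree.query_ball_point(xy, r=rmax + 1e-9)
        for i, cand in enumerate(neighbors):
            if not cand:
                continue
            cand = np.asarray(cand)
            d = np.hypot(*(centers[cand] - xy[i]).T)
            hit = cand[d <= radii[cand] + 1e-12]
            if len(hit) == 0:
                continue
            dh = d[d <= radii[cand] + 1e-12]
            order = np.lexsort((ids[hit], dh))  # nearest centre, then lower id
            cell[i] = ids[hit[order[0]]]
    df["cell_id"] = cell
    return TranscriptTable(df)


def build_matrix(transcripts: TranscriptTable) -> CellByGene:
    """Count assigned transcripts into a sparse cells × genes matrix.

    Unassigned transcripts (cell_id < 0) are excluded; the matrix total
    equals the number of assigned transcripts.
    """
    if "cell_id" not in transcripts.data.columns:
        raise ValueError("transcripts carry no cell assignment")
    assigned = transcripts.assigned
    if len(assigned) == 0:
        raise ValueError("no assigned transcripts")
    cells = np.sort(assigned["cell_id"].unique())
    genes = np.sort(assigned["gene"].unique())
    ci = pd.Series(np.arange(len(cells)), index=cells)
    gi = pd.Series(np.arange(len(genes)), index=genes)
    mat = sp.coo_matrix(
        (np.ones(len(assigned), dtype=int),
         (ci[assigned["cell_id"]].to_numpy(), gi[assigned["gene"]].to_numpy())),
        shape=(len(cells), len(genes)))
    csr = mat.tocsr()
    csr.sum_duplicates()
    return CellByGene(cells, genes, csr)


@dataclass
class QCReport:
    protocol: str
    rule: str
    n_in: int
    n_kept: int

    @property
    def n_dropped(self) -> int:
        return self.n_in - self.n_kept

    @property
    def kept_fraction(self) -> float:
        return self.n_kept / self.n_in if self.n_in else float("nan")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d.update(n_dropped=self.n_dropped, kept_fraction=self.kept_fraction)
        return d


def qc_filter(cbg: CellByGene, protocol: str = "hybiss", *,
              min_genes: int = 3, min_counts: int = 5,
              min_counts_scrinshot: int = 25,
              min_counts_copd: int = 8) -> tuple[CellByGene, QCReport]:
    """Apply a per-protocol cell QC filter (strict-inequality cutoffs).

    The high-plex rule drops a cell when it has fewer than ``min_genes``
    distinct genes OR fewer than ``min_counts`` total transcripts (the OR
    reading removes single-gene cells with few counts, which an AND reading
    would keep).  The active rule is recorded in the report.
    """
    totals = cbg.totals()
    if protocol == "hybiss":
        keep = (cbg.genes_detected() >= min_genes) & (totals >= min_counts)
        rule = f"drop if (distinct genes < {min_genes}) OR (total counts < {min_counts})"
    elif protocol == "scrinshot":
        keep = totals >= min_counts_scrinshot
        rule = f"drop if total counts < {min_counts_scrinshot}"
    elif protocol == "scrinshot_copd":
        keep = totals >= min_counts_copd
        rule = f"drop if total counts < {min_counts_copd}"
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    report = QCReport(protocol, rule, cbg.shape[0], int(keep.sum()))
    if report.n_kept == 0:
        raise ValueError(f"QC dropped all cells ({report.to_dict()})")
    filtered = CellByGene(cbg.cell_ids[keep], cbg.gene_ids, cbg.counts[keep])
    return filtered, report
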