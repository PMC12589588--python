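"""Barcode calling for combinatorial in-situ sequencing spots.

Each spot carries an R (rounds) × C (channels) intensity matrix.  Decoding
takes, per round, the channel of highest intensity (ties to the lowest
channel index) and looks the resulting channel sequence up in the codebook.
Spots whose sequence matches no barcode are dropped and counted.

Per-round spot quality is the called channel's intensity divided by the sum
of the intensities in all C channels of that round, which ranges from 1/C
(all channels equal) to 1 (one-hot).  The per-spot quality aggregates rounds
by minimum (conservative) or mean; spots below ``min_quality`` are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Codebook, SpotIntensitySeries, TranscriptTable

__all__ = ["spot_quality", "decode_spots", "DecodeReport"]


def spot_quality(intensity_row: np.ndarray) -> float:
    """Per-round quality of one spot: max(channel) / sum(channels).

    Bounded in [1/C, 1] for any row with at least one positive channel.
    Undefined (raises) for an all-zero row; callers treat such rounds as
    undecodable rather than calling this.
    """
    row = np.asarray(intensity_row, dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValueError("quality undefined for an all-zero intensity row")
    return float(row.max() / total)


@dataclass
class DecodeReport:
    n_spots: int = 0
    n_matched: int = 0
    n_unmatched: int = 0
    n_undecodable: int = 0    # a round with all-zero intensities
    n_low_quality: int = 0
    min_quality: float = 0.0
    quality_aggregate: str = "min"

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def decode_spots(series: SpotIntensitySeries, codebook: Codebook,
                 min_quality: float = 0.5,
                 quality_aggregate: str = "min") -> tuple[TranscriptTable, DecodeReport]:
    """Call genes from per-round intensities against a codebook.

    Returns the decoded transcript table (matched, quality-passing spots
    only) and a report with drop counts.
    """
    if series.rounds != codebook.rounds or series.channels != codebook.channels:
        raise ValueError(
            f"intensity dimensions (R={series.rounds}, C={series.channels}) do not "
            f"match codebook (R={codebook.rounds}, C={codebook.channels})")
    if quality_aggregate not in ("min", "mean"):
        raise ValueError("quality_aggregate must be 'min' or 'mean'")

    inten = series.intensity                      # (n, R, C)
    report = DecodeReport(n_spots=len(series), min_quality=min_quality,
                          quality_aggregate=quality_aggregate)

    round_sums = inten.sum(axis=2)                # (n, R)
    decodable = (round_sums > 0).all(axis=1)
    report.n_undecodable = int((~decodable).sum())

    # argmax ties break to the lowest channel index by numpy convention
    calls = inten.argmax(axis=2)                  # (n, R)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_round_q = inten.max(axis=2) / round_sums
    agg = per_round_q.min(axis=1) if quality_aggregate == "min" else per_round_q.mean(axis=1)

    lookup = codebook.lookup()
    rows = []
    for i in np.flatnonzero(decodable):
        gene = lookup.get(tuple(calls[i]))
        if gene is None:
            report.n_unmatched += 1
            continue
        if agg[i] < min_quality:
            report.n_low_quality += 1
            continue
        rows.append((int(series.spot_ids[i]), series.xy[i, 0], series.xy[i, 1],
                     gene, float(agg[i])))
    report.n_matched = len(rows)
    df = pd.DataFrame(rows, columns=["spot_id", "x", "y", "gene", "quality"])
    if df.empty:
        df = pd.DataFrame({"spot_id": pd.Series(dtype=int), "x": pd.Series(dtype=float),
                           "y": pd.Series(dtype=float), "gene": pd.Series(dtype=str),
                           "quality": pd.Series(dtype=float)})
    return TranscriptTable(df), report
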