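import numpy as np
import pandas as pd
import pytest

from lungscape.io import CellMap, Codebook
from lungscape.synthetic import SynthConfig, generate_tissue


@pytest.fixture(scope="session")
def codebook() -> Codebook:
    """30-gene codebook, 5 rounds x 4 channels, distinct barcodes."""
    rng = np.random.default_rng(11)
    entries: dict[str, tuple[int, ...]] = {}
    seen = set()
    while len(entries) < 30:
        bc = tuple(int(c) for c in rng.integers(0, 4, size=5))
        if bc not in seen:
            seen.add(bc)
            entries[f"G{len(entries):02d}"] = bc
    return Codebook(5, 4, entries)


@pytest.fixture(scope="session")
def tissue():
    """One default synthetic sample: (CellMap, TranscriptTable, NucleiSet,
    GeometryAnnotation).  Session-scoped: treated as read-only."""
    return generate_tissue(SynthConfig(), seed=101)


@pytest.fixture(scope="session")
def small_tissue():
    cfg = SynthConfig(n_epithelial=120, n_alveolar=200)
    return generate_tissue(cfg, seed=102)


def two_block_cellmap(n_per_block: int = 500, p1: float = 0.8, p2: float = 0.2,
                      seed: int = 0) -> tuple[CellMap, np.ndarray]:
    """Two spatially disjoint blocks with mixtures p/(1-p) of types A/B;
    returns the map and the true block label per cell."""
    rng = np.random.default_rng(seed)
    xy1 = rng.uniform(0, 500, (n_per_block, 2))
    xy2 = rng.uniform([600, 0], [1100, 500], (n_per_block, 2))
    t1 = np.where(rng.uniform(size=n_per_block) < p1, "A", "B")
    t2 = np.where(rng.uniform(size=n_per_block) < p2, "A", "B")
    df = pd.DataFrame({
        "cell_id": np.arange(2 * n_per_block),
        "x": np.r_[xy1[:, 0], xy2[:, 0]],
        "y": np.r_[xy1[:, 1], xy2[:, 1]],
        "type_label": np.r_[t1, t2],
        "sample_id": "s1",
    })
    truth = np.r_[np.zeros(n_per_block, dtype=int), np.ones(n_per_block, dtype=int)]
    return CellMap(df), truth
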