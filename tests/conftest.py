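import numpy as np
import pytest

from qtlspan import CrossData, GeneticMap, markers_dataframe
from qtlspan.cross import F2


@pytest.fixture
def two_chrom_map() -> GeneticMap:
    """Two chromosomes x three markers, 10 cM spacing."""
    rows = []
    for c in ("1", "2"):
        for i in range(3):
            rows.append((f"x{c}_{i}", c, 10.0 * (i + 1), int(2e6 * (i + 1))))
    return GeneticMap(markers_dataframe(rows))


def random_cross(
    seed: int,
    n_mice: int = 15,
    gmap: GeneticMap | None = None,
    missing_rate: float = 0.15,
) -> CrossData:
    """Small random cross with missing genotypes (not Mendelian; stress fixture)."""
    if gmap is None:
        rows = []
        for c in ("1", "2"):
            for i in range(3):
                rows.append((f"x{c}_{i}", c, 10.0 * (i + 1), int(2e6 * (i + 1))))
        gmap = GeneticMap(markers_dataframe(rows))
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 3, size=(n_mice, gmap.n_markers)).astype(np.int8)
    g[rng.random(g.shape) < missing_rate] = -1
    y = rng.normal(10.0, 2.0, n_mice)
    y = np.maximum(y, 1e-6)
    return CrossData(
        gmap=gmap,
        genotypes=g,
        mouse_ids=tuple(f"m{i}" for i in range(n_mice)),
        origins=(F2,) * n_mice,
        phenotype=y,
    )
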