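import numpy as np
import pandas as pd
import pytest

from napchip import (
    Gene,
    GeneSet,
    GenomeAssembly,
    GenomicInterval,
    PeakTable,
)
from napchip.peaks import PEAK_COLUMNS


@pytest.fixture
def toy_genome() -> GenomeAssembly:
    """1-kb deterministic contig: alternating 100-bp AT-rich / GC-rich blocks."""
    rng = np.random.default_rng(1234)
    bases = np.array(list("ATGC"))
    blocks = []
    for i in range(10):
        at = 0.8 if i % 2 == 0 else 0.3
        p = [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2]
        blocks.append("".join(bases[rng.choice(4, size=100, p=p)]))
    return GenomeAssembly({"c1": "".join(blocks)})


@pytest.fixture
def toy_genes(toy_genome) -> GeneSet:
    """Three genes on c1: [100,300), [450,550), [700,900)."""
    spans = [(100, 300), (450, 550), (700, 900)]
    return GeneSet([
        Gene(GenomicInterval("c1", s, e, "+"), f"g{i + 1:03d}", f"product {i + 1}")
        for i, (s, e) in enumerate(spans)
    ])


def make_peak_table(rows) -> PeakTable:
    """rows: iterable of (peak_id, contig, start, end, summit, fe)."""
    df = pd.DataFrame(
        [dict(zip(PEAK_COLUMNS[:6], r), q_value=np.nan, replicate_support=1)
         for r in rows],
        columns=PEAK_COLUMNS)
    return PeakTable(df)


@pytest.fixture
def toy_peaks() -> PeakTable:
    return make_peak_table([
        ("p1", "c1", 0, 120, 50, 1.5),
        ("p2", "c1", 300, 500, 400, 2.0),
        ("p3", "c1", 600, 990, 800, 3.4),
    ])
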