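import numpy as np
import pandas as pd
import pytest

from structura.grids import ElevationGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def flat_chm():
    """Constant 12 m canopy on 1 m cells."""
    return ElevationGrid(np.full((8, 8), 12.0), 1.0)


@pytest.fixture
def counts_table():
    """Small clean long-format count table: 3 sites x 3 levels."""
    rows = []
    rng = np.random.default_rng(7)
    for s, base in zip(["A", "B", "C"], [2, 5, 9]):
        for level in ("plant", "beetle", "bird"):
            for t in range(base + 3):
                for u in ("U1", "U2"):
                    rows.append(
                        {
                            "site": s,
                            "trophic_level": level,
                            "unit": u,
                            "date": "2020-06-01",
                            "taxon": f"{level}_{t}",
                            "count": int(rng.integers(1, 8)),
                        }
                    )
    return pd.DataFrame(rows)
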