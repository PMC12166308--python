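import numpy as np
import pandas as pd
import pytest

from spotsnv import synthetic
from spotsnv.types import SpotTable


def lattice_spots(m: int, umi: int = 100) -> SpotTable:
    """m x m integer lattice with uniform depth."""
    xs, ys = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    return SpotTable(
        pd.DataFrame(
            {
                "barcode": [f"s{x}_{y}" for x, y in zip(xs.ravel(), ys.ravel())],
                "x": xs.ravel(),
                "y": ys.ravel(),
                "total_umi": umi,
            }
        )
    )


@pytest.fixture(scope="session")
def section():
    """Default synthetic section (shared; treat as read-only)."""
    return synthetic.generate_section(seed=1)


@pytest.fixture(scope="session")
def toy_genome():
    return synthetic.generate_toy_genome(seed=1)


@pytest.fixture(scope="session")
def toy_genome_dir(toy_genome, tmp_path_factory):
    d = tmp_path_factory.mktemp("toy")
    synthetic.write_toy_genome(toy_genome, d)
    return d
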