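import numpy as np
import pandas as pd
import pytest

from beigechrom import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A shared desk-scale cohort: 21 samples x 40 cells, no collisions.

    Depth lognormal(6, 0.6) keeps the 10-kb window matrix sparse at this
    genome size.
    """
    design = synthetic.default_design(n_cells_per_sample=40)
    genome, truth, frags, cell_truth = synthetic.simulate_atac(
        design=design, depth_lognormal=(6.0, 0.6), seed=2
    )
    return genome, truth, frags, cell_truth


@pytest.fixture(scope="session")
def lipid_design():
    rows = [(f"{c}{d}r{r}", c, d, r)
            for c in ("cold", "CL") for d in (1, 3, 7) for r in (1, 2, 3)]
    rows += [(f"RT0r{r}", "RT", 0, r) for r in (1, 2, 3)]
    return pd.DataFrame(rows, columns=["sample", "condition", "day", "replicate"])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
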