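import numpy as np
import pandas as pd
import pytest

from methylhist import (
    FeatureParams,
    MethylomeTable,
    SimConfig,
    build_training_set,
    default_params,
    simulate_training_regions,
    train,
)
from methylhist.io import METHYLOME_COLUMNS


def make_table(positions, mc, t, sample_id="s", chrom="chr1", strand="+", context="CG"):
    """Build a MethylomeTable from parallel arrays (test helper)."""
    positions = np.asarray(positions)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "strand": strand,
            "context": context,
            "mc": np.asarray(mc),
            "t": np.asarray(t),
        }
    )[METHYLOME_COLUMNS]
    return MethylomeTable(sample_id=sample_id, sites=df)


@pytest.fixture(scope="session")
def cg_params() -> FeatureParams:
    return default_params("CG")


@pytest.fixture(scope="session")
def training_genome():
    """Labeled synthetic training genome shared across the suite."""
    cfg = SimConfig(sim_class=1, n_dmr=200, n_non_dmr=300, seed=101)
    return simulate_training_regions(cfg)


@pytest.fixture(scope="session")
def trained_model(training_genome, cg_params):
    g1, g2, regions = training_genome
    ts = build_training_set(g1, g2, regions, cg_params)
    return train(ts, seed=0, params=cg_params)
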