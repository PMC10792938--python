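import numpy as np
import pandas as pd
import pytest

from epirevert.methylome import MethylomeTrack
from epirevert.simulate import SimulationConfig, generate_genome, generate_methylomes


def make_track(positions, meths, covs=None, chrom="chr1", line="L1", state="parental"):
    positions = np.asarray(positions)
    if covs is None:
        covs = np.full(len(positions), 30)
    df = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "meth": meths, "cov": covs}
    )
    return MethylomeTrack(line_id=line, state=state, records=df)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_chroms=2,
        chrom_length=500_000,
        n_cpg_islands=8,
        n_genes=20,
        n_planted_dmrs=15,
        n_vpr=300,
        n_vpp=60,
        n_vppr=120,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_methylomes(small_genome, small_config):
    return generate_methylomes(small_genome, small_config)
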