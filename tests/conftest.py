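import numpy as np
import pandas as pd
import pytest

from mkregnet import synth


@pytest.fixture(scope="session")
def small_config() -> synth.SimConfig:
    """Scaled-down study conditions used by most unit tests."""
    return synth.SimConfig(
        seed=7,
        n_chrom=1,
        chrom_length=1_000_000,
        n_genes=30,
        n_sites=40,
        n_tags=60_000,
        enrichment_pi=0.7,
    )


@pytest.fixture(scope="session")
def small_world(small_config) -> synth.SyntheticWorld:
    return synth.simulate_world(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_loci(rows) -> pd.DataFrame:
    """Helper: build a locus frame from (chrom, start, end[, max_coverage])."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "max_coverage"][: len(rows[0])])
    if "max_coverage" not in df:
        df["max_coverage"] = 1
    df.insert(0, "locus_id", [f"locus_{i:05d}" for i in range(len(df))])
    df["summit"] = (df["start"] + df["end"]) // 2
    return df
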