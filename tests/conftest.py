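import numpy as np
import pandas as pd
import pytest

from chromdyn import Genome, SimulationConfig


@pytest.fixture
def genome_small() -> Genome:
    return Genome({"chr": 100_000})


@pytest.fixture
def genome_1mb() -> Genome:
    return Genome({"chr": 1_000_000})


@pytest.fixture
def background_config(genome_1mb) -> SimulationConfig:
    return SimulationConfig(genome=genome_1mb, background_rate=0.05, seed=1)


def intervals(*rows) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=["chrom", "start", "end"])


@pytest.fixture
def make_intervals():
    return intervals
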