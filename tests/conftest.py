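import numpy as np
import pandas as pd
import pytest

from lncsig.features import FeatureTable
from lncsig.synthetic_data import (
    SimulationConfig,
    planted_feature_table,
    simulate_transcriptome,
)

GTF_TEXT = """\
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t501\t560\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
chr1\tsrc\texon\t601\t660\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
chr1\tsrc\texon\t701\t800\t.\t+\t.\tgene_id "g1"; transcript_id "t3";
"""


@pytest.fixture
def gtf_file(tmp_path):
    path = tmp_path / "models.gtf"
    path.write_text(GTF_TEXT)
    return path


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=1000)])
    return {"chr1": seq}


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated transcriptome shared across tests (read-only)."""
    return simulate_transcriptome(SimulationConfig(n_coding=40, n_noncoding=15, seed=7))


@pytest.fixture(scope="session")
def planted_table():
    """n=200, p=10, one strongly planted feature f01, balanced classes."""
    return planted_feature_table(n=200, p=10, effect=2.0, skew=0.5, seed=11)


@pytest.fixture
def labeled_table():
    rng = np.random.default_rng(5)
    n = 60
    y = np.r_[np.ones(20, dtype=int), np.zeros(40, dtype=int)]
    df = pd.DataFrame(
        {
            "sig": y + 0.3 * rng.standard_normal(n),
            "noise1": rng.standard_normal(n),
            "noise2": rng.standard_normal(n),
        },
        index=[f"t{i}" for i in range(n)],
    )
    labels = pd.Series(np.where(y == 1, "lncRNA", "Other"), index=df.index)
    return FeatureTable(df, labels)
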