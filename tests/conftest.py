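import json
from pathlib import Path

import pandas as pd
import pytest

from cremap.pipeline import PipelineConfig, run_all


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full synthetic pipeline run shared by integration tests."""
    outdir = tmp_path_factory.mktemp("demo_run")
    config = PipelineConfig(n_genes=400, seed=1)
    manifest = run_all(config, outdir)
    return {"config": config, "outdir": Path(outdir), "manifest": manifest}


@pytest.fixture(scope="session")
def demo_truth(demo_run):
    return json.loads((demo_run["outdir"] / "truth.json").read_text())


@pytest.fixture(scope="session")
def demo_assignments(demo_run):
    return pd.read_csv(demo_run["outdir"] / "assignments.tsv", sep="\t", index_col=0)


#: the published per-cluster gene counts used as the accounting fixture
PUBLISHED_CLUSTER_SIZES = {
    "A": 19, "B": 24, "C": 16, "D": 36, "E": 50,
    "F": 36, "G": 26, "H": 26, "X": 17,
}
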