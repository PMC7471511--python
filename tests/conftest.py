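import numpy as np
import pandas as pd
import pytest

from modoc.io_formats import ExpressionMatrix
from modoc.pipeline import RunConfig, run_pipeline
from modoc.synthetic import SyntheticConfig, simulate_expression


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    """The default study conditions, seed 1."""
    return SyntheticConfig(rng_seed=1)


@pytest.fixture(scope="session")
def synth_expression(default_config):
    """(ExpressionMatrix, truth ModulePartition) at default conditions."""
    return simulate_expression(default_config)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full pipeline run at default conditions, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(RunConfig(out_dir=str(out), seed=1))


def make_expression(values: np.ndarray, genes, time_points, n_donors=1) -> ExpressionMatrix:
    """Small hand-built expression matrix: one column per (tp, donor)."""
    samples, meta = [], {}
    for tp in time_points:
        for d in range(1, n_donors + 1):
            name = f"{tp}.{d}"
            samples.append(name)
            meta[name] = {"time_point": tp, "donor": d, "condition": "standard"}
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        pd.DataFrame.from_dict(meta, orient="index").rename_axis("sample"),
    )
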