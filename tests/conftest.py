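import numpy as np
import pandas as pd
import pytest

from npqmap.config import PipelineConfig

#: Panel-mean kinetic parameters used throughout the tests.
PANEL_PARAMS = dict(
    a_npq_i=2.8,
    k_ind=0.58,
    a_npq_r=1.91,
    k_rel=5.09,
    b_npq=0.89,
    a_phi=0.3,
    k_rec=5.08,
    b_phi=0.2,
    fvfm=0.75,
)


@pytest.fixture(scope="session")
def panel_params():
    return dict(PANEL_PARAMS)


def tiny_config(seed: int = 0, **overrides) -> PipelineConfig:
    """A minimal pipeline configuration for fast integration tests."""
    base = dict(
        n_accessions=60,
        n_checks=2,
        n_blocks=4,
        rows=8,
        cols=9,
        discs_per_plot=2,
        n_snps=400,
        n_extra_genes=120,
        residual_structure="independent",
        seed=seed,
    )
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """One shared tiny end-to-end pipeline run."""
    from npqmap.pipeline import run_pipeline

    cfg = tiny_config(seed=11)
    return run_pipeline(cfg, tmp_path_factory.mktemp("tiny_run"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
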