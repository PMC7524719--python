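import warnings

import pytest

from palmfrug import PipelineConfig, SyntheticWorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact but fully featured synthetic world shared across tests."""
    cfg = SyntheticWorldConfig(n_countries=40, n_palm_species=600,
                               n_mammal_species=400, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_world(cfg)


@pytest.fixture()
def small_pipeline_config(tmp_path):
    return PipelineConfig(
        outdir=str(tmp_path / "out"),
        seed=5,
        world=dict(n_countries=40, n_palm_species=600, n_mammal_species=400),
        n_sims=100,
        ctmc_sim={
            "up": [0.005, 0.008, 0.010, 0.012, 0.015],
            "down": [0.003, 0.004, 0.004, 0.005, 0.0],
            "start": [0.55, 0.12, 0.12, 0.11, 0.08, 0.02],
            "datasets": [
                {"n_species": 1500, "elapsed_years": 12.0, "label": "mammals-12y"},
                {"n_species": 400, "elapsed_years": 33.0, "label": "ungulates-33y"},
            ],
        },
    )
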