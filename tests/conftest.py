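import numpy as np
import pytest

from synercomb import io as sio
from synercomb.pipeline import PipelineConfig, stage_featurize, stage_score, stage_simulate
from synercomb.simulate import SimulationConfig, simulate_study


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


SMALL_SIM = dict(n_genes=40, panel_size=30, n_cell_lines=6, n_drugs=6, seed=42)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated screen (6 cell lines x 15 drug pairs)."""
    return simulate_study(SimulationConfig(**SMALL_SIM))


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """The small screen scored and featurized on disk."""
    wd = tmp_path_factory.mktemp("small_run")
    cfg = PipelineConfig(workdir=str(wd), seed=42,
                         simulation=SimulationConfig(**SMALL_SIM),
                         thresholds=(0.0, 20.0))
    study = stage_simulate(cfg)
    scores = stage_score(cfg)
    X, schema, split = stage_featurize(cfg)
    return {"config": cfg, "study": study, "scores": scores, "X": X,
            "schema": schema, "split": split}
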