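import numpy as np
import pytest

from pitsync import SimulationConfig
from pitsync.pipeline import PipelineConfig, analyze_dataset, simulate_group

#: Study conditions: 7 replicate slice experiments per genotype arm,
#: ~60 cells each; the coupled arm has gap junctions enabled, the
#: uncoupled arm does not. Tonic arms add coupled slow baseline
#: fluctuations (the short-range scenario).
N_DATASETS_PER_ARM = 7


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def study_pairs(pipeline_config):
    """Pooled per-window pair correlations for one simulated study arm.

    ``study_pairs(replicate, coupled, tonic)`` returns a dict mapping window
    name -> list of PairCorrelation pooled over the arm's 7 datasets.
    Results are cached across tests.
    """
    cache: dict = {}

    def build(replicate: int, coupled: bool, tonic: bool = False):
        key = (replicate, coupled, tonic)
        if key in cache:
            return cache[key]
        seed = 100 + 2 * replicate + (0 if coupled else 1)
        base = SimulationConfig(coupling_enabled=coupled, tonic_coupling=tonic)
        datasets = simulate_group(base, N_DATASETS_PER_ARM, "arm", seed)
        pooled = {name: [] for name, _, _ in pipeline_config.windows}
        for ds in datasets:
            per = analyze_dataset(
                ds, pipeline_config, group="coupled" if coupled else "uncoupled"
            )
            for name in pooled:
                pooled[name].extend(per[name])
        cache[key] = pooled
        return pooled

    return build


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
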