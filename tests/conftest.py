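import warnings

import numpy as np
import pytest

from connsweep import synth
from connsweep.pipeline import RunConfig, run_pipeline

warnings.filterwarnings("ignore", message="rewiring achieved", category=RuntimeWarning)

#: master seed for the deterministic test cohort
COHORT_SEED = 7


@pytest.fixture(scope="session")
def ground_truth_model():
    return synth.build_ground_truth(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def small_cohort():
    """An 6/6/6-subject cohort for generator-level checks."""
    cfg = synth.CohortConfig(group_sizes={"CI": 6, "NCI": 6, "HC": 6})
    return synth.generate_cohort(cfg, master_seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-size cohort (36 CI / 30 NCI / 48 HC)."""
    return synth.generate_cohort(synth.CohortConfig(), master_seed=COHORT_SEED)


@pytest.fixture(scope="session")
def full_pipeline_run(tmp_path_factory):
    """One end-to-end run of the default pipeline, shared across tests.

    Uses 20 null networks per grid point, the scale at which the whole sweep
    over the candidate grid stays tractable on a single core.
    """
    out = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(out_dir=str(out), master_seed=COHORT_SEED, n_null=20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        report = run_pipeline(cfg)
    return cfg, report, out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
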