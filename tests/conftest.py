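import warnings

import numpy as np
import pytest

from cnvpopscan.genome import make_windowed_genome
from cnvpopscan.pipeline import demo_config, run_pipeline

DEMO_SEED = 7


@pytest.fixture(scope="session")
def demo_state(tmp_path_factory):
    """One full demo-cohort pipeline run shared by the whole suite.

    5 populations x 10 samples, ~2,500 windows of 800 bp, 20 planted regions,
    50 reads/window, fixed seed.
    """
    outdir = tmp_path_factory.mktemp("demo_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest, state = run_pipeline(demo_config(DEMO_SEED), outdir, return_state=True)
    state["manifest"] = manifest
    state["outdir"] = outdir
    return state


@pytest.fixture
def flat_genome():
    """A small single-chromosome genome with no masking (40 windows of 800 bp)."""
    return make_windowed_genome({"chr1": 32_000}, window_size=800, gc_profile_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_527)
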