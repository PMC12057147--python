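import numpy as np
import pytest

from lc8screen import synth


@pytest.fixture(scope="session")
def bound_run_dir(tmp_path_factory):
    """A 3-structure 1-client run with the client in the groove, no noise."""
    cfg = synth.FixtureConfig(n_structures=3, client_count=1, bound=True, seed=11)
    return synth.gen_run_dir(cfg, tmp_path_factory.mktemp("runs") / "bound_1c"), cfg


@pytest.fixture(scope="session")
def unbound_run_dir(tmp_path_factory):
    """A 2-structure 1-client run with the client displaced 50 Å."""
    cfg = synth.FixtureConfig(
        n_structures=2, client_count=1, bound=False, seed=12,
        score_means={"conf": 0.55, "plddt": 60.0, "ltop": 18.0, "ptol": 22.0,
                     "dimer": 1.2},
    )
    return synth.gen_run_dir(cfg, tmp_path_factory.mktemp("runs") / "unbound_1c"), cfg


@pytest.fixture(scope="session")
def labeled_vectors():
    """A moderately separable labeled score dataset (fixed seed)."""
    return synth.gen_score_dataset(80, 80, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
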