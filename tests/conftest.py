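import numpy as np
import pytest

from netstab.cohort import StudyDesign, generate_cohort, run_sample_simulations


class ZeroRng:
    """Stand-in random stream whose uniform draws are always the midpoint."""

    def random(self, size=None):
        return 0.5 if size is None else np.full(size, 0.5)

    def uniform(self, low, high, size=None):
        return 0.0 if size is None else np.zeros(size)


@pytest.fixture
def zero_rng():
    return ZeroRng()


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(
        n_subjects=4, n_sessions=2, n_subsamples=2,
        n_volumes=16, n_b0=2, n_sims=4, n_nodes=8, rank=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return generate_cohort(small_design, seed=7)


@pytest.fixture(scope="session")
def small_connectomes(small_cohort):
    d = small_cohort.design
    conns = {}
    for sid in small_cohort.sample_ids():
        for pipeline in d.pipelines:
            for mode in d.modes:
                conns.update(
                    run_sample_simulations(
                        small_cohort, sid, pipeline, mode,
                        n_sims=d.n_sims, base_seed=11,
                    )
                )
    return conns
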