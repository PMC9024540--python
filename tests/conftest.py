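import numpy as np
import pytest

import ensemblesdm as esdm


@pytest.fixture(scope="session")
def study():
    """A clean virtual-species study: narrow-niche specialist, 200 presences,
    one correlated layer pair, contraction + expansion scenarios."""
    return esdm.simulate_study(seed=1, grid_shape=(100, 100), n_presences=200)


@pytest.fixture(scope="session")
def suite_bundle(study):
    """Thin -> filter -> pseudo-absences -> 9x3 model suite, fitted once."""
    stack = study.stack
    occ = esdm.thin_occurrences(study.occurrences, stack)
    report = esdm.select_uncorrelated(esdm.correlation_matrix(stack))
    pa = esdm.sample_pseudo_absences(stack, occ, 1000, seed=2)
    dataset = esdm.build_dataset(stack, occ, pa, report.retained)
    esdm.make_splits(dataset, train_frac=0.8, reps=3, seed=3)
    suite = esdm.fit_suite(dataset, seed=4)
    return {"study": study, "stack": stack, "occurrences": occ,
            "retained": report.retained, "dataset": dataset, "suite": suite}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
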