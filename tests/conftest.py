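import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smurfdeconv import synth

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    """Mid-size synthetic experiment shared across test modules."""
    truth = synth.generate_gene_truth(6000, seed=11)
    expt = synth.simulate_counts(truth, seed=12)
    sets, hallmark_map = synth.build_genesets(truth, seed=13)
    return truth, expt, sets, hallmark_map


@pytest.fixture(scope="session")
def null_bundle():
    """All-null experiment (no state, age or interaction effects)."""
    truth = synth.generate_gene_truth(2000, class_fractions={}, seed=21)
    expt = synth.simulate_counts(truth, seed=22)
    return truth, expt


@pytest.fixture(scope="session")
def smurf_de(bundle):
    from smurfdeconv import de

    _, expt, _, _ = bundle
    return de.nb_wald_test(expt.counts, expt.meta, contrast="smurf")


def make_truth_from_table(table, gamma=synth.DISPERSION_AGE_GAMMA):
    return synth.GeneTruth(table=table, gamma=gamma)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
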