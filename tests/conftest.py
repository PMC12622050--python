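import numpy as np
import pytest

from novelforge import sampler as sp
from novelforge import surrogates as sg


def random_canonical_sequence(rng, length):
    from novelforge.structio import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture(scope="session")
def surrogate_structures():
    """20 surrogate-predicted structures of mixed composition."""
    rng = np.random.default_rng(42)
    structs = []
    for i in range(20):
        seq = random_canonical_sequence(rng, int(rng.integers(20, 45)))
        structs.append(sg.toy_structure_predictor(seq, f"surr{i}"))
    return structs


@pytest.fixture(scope="session")
def suite():
    return sg.surrogate_suite()


@pytest.fixture(scope="session")
def energy_model(suite):
    return sp.EnergyModel(
        likelihood_scorer=suite.likelihood_scorer,
        contact_scorer=suite.contact_scorer,
    )


@pytest.fixture(scope="session")
def trend_model(suite):
    """Contact-weighted toy energy: refinement on this landscape climbs
    toward contact-dense (hence compact) sequences, giving the selection
    loops a real gradient."""
    return sp.EnergyModel(
        likelihood_scorer=suite.likelihood_scorer,
        contact_scorer=suite.contact_scorer,
        likelihood_weight=0.5,
        contact_weight=2.0,
    )


@pytest.fixture(scope="session")
def trend_sampler_cfg():
    return sp.SamplerConfig(
        n_replicas=2, temperatures=(0.3, 1.5),
        steps_per_replica=20, swap_interval=5, seed=11,
    )


@pytest.fixture(scope="session")
def fragment_library(trend_model, trend_sampler_cfg, suite):
    """Small shared fragment library (deliberately lightly optimized so
    downstream selection has headroom)."""
    from novelforge.genalg import generate_fragment_library

    return generate_fragment_library(
        n=60, length=40, cfg=trend_sampler_cfg, model=trend_model,
        structure_predictor=suite.structure_predictor,
    )


@pytest.fixture(scope="session")
def refdb():
    library, tsv = sg.make_fixture_refdb(3, 2, seed=4)
    return library, tsv
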