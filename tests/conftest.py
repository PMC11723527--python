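import numpy as np
import pytest

import domainseg as ds


@pytest.fixture(scope="session")
def two_domain_protein():
    """A seeded two-domain synthetic protein with planted truth."""
    spec = ds.SyntheticSpec(n_domains=2, domain_sizes=(80, 90), seed=11)
    model, pae, truth, ss = ds.make_protein(spec)
    return model, pae, truth, ss


@pytest.fixture(scope="session")
def trained_tiny(suite30):
    """The tiny network trained once on the 30-protein suite (shared by the
    training-behaviour unit tests and the recovery acceptance test)."""
    records = [
        ds.ProteinRecord(p.channels, p.truth, p.cluster_id) for p in suite30
    ]
    cfg = ds.TrainConfig(epochs=8, seed=1, batch_size=1)
    return ds.train(records, ds.NetworkConfig.tiny(0), cfg), records, cfg


@pytest.fixture(scope="session")
def suite30():
    from domainseg.synthetic import make_suite

    return make_suite(30, seed=7)
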