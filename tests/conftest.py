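"""Shared fixtures: synthetic compendia and trained VAEs.

Training is session-scoped so the expensive fits happen once.  The
"default" compendium (1,000 samples x 300 genes, 20 experiments) is the
study condition used by the simulation studies; the "strong" compendium
doubles the within-experiment group effect so template experiments carry
an unambiguous two-group signature.
"""

import numpy as np
import pytest

import latentsim as ls


@pytest.fixture(scope="session")
def default_spec():
    return ls.SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def default_data(default_spec):
    return ls.generate_compendium(default_spec)


@pytest.fixture(scope="session")
def default_comp(default_data):
    return default_data[0]


@pytest.fixture(scope="session")
def default_truth(default_data):
    return default_data[1]


@pytest.fixture(scope="session")
def default_vae(default_comp):
    cfg = ls.VAEConfig(input_dim=default_comp.n_genes, intermediate_dim=100,
                       latent_dim=10, epochs=30, seed=11)
    return ls.ExpressionVAE(default_comp, cfg).fit()


@pytest.fixture(scope="session")
def strong_data():
    spec = ls.SyntheticSpec(group_effect=2.0, seed=7)
    return ls.generate_compendium(spec)


@pytest.fixture(scope="session")
def strong_comp(strong_data):
    return strong_data[0]


@pytest.fixture(scope="session")
def strong_truth(strong_data):
    return strong_data[1]


@pytest.fixture(scope="session")
def strong_vae(strong_comp):
    cfg = ls.VAEConfig(input_dim=strong_comp.n_genes, intermediate_dim=100,
                       latent_dim=10, epochs=30, seed=7)
    return ls.ExpressionVAE(strong_comp, cfg).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def template_group_labels(record, truth):
    """Group labels of a simulated experiment, recovered from its template."""
    return [truth.group_of[s.split("_", 1)[1]] for s in record.member_sample_ids]
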