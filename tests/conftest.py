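import numpy as np
import pandas as pd
import pytest

import omniflux as om


@pytest.fixture(scope="session")
def small_annotation():
    return om.generate_annotation(n_genes=300, ontology_size=20, seed=11)


@pytest.fixture(scope="session")
def design():
    return om.ExperimentDesign(seed=11)


@pytest.fixture(scope="session")
def truth(small_annotation, design):
    annotation, _ = small_annotation
    return om.generate_truth(design, annotation)


@pytest.fixture(scope="session")
def noiseless_truth(small_annotation, design):
    """Truth with no replicate noise: layers follow base mRNA x propensity exactly."""
    annotation, _ = small_annotation
    cfg = om.EffectConfig(replicate_noise_sd=0.0, process_effects={},
                          gene_propensity_effects={})
    return om.generate_truth(design, annotation, cfg)


@pytest.fixture(scope="session")
def toy(design):
    return om.generate_toy_ecmodel(seed=17, design=design)


def abundance(frame: pd.DataFrame, layer="protein", units="molecules_per_cell"):
    return om.AbundanceMatrix(frame, layer=layer, units=units)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
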