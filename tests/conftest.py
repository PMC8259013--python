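import numpy as np
import pandas as pd
import pytest

import epimarray as em


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured simulation: every context class, planted
    methylation/expression effects, spike-ins."""
    return em.SimulationConfig(n_mrna=120, n_lncrna=24, n_spikein=6, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    annotation, genes = em.generate_annotation(small_config)
    arrays, truth = em.generate_intensities(small_config, annotation)
    return {"config": small_config, "annotation": annotation, "genes": genes,
            "arrays": arrays, "truth": truth}


@pytest.fixture(scope="session")
def quantified(small_dataset):
    return em.quantify(small_dataset["arrays"])


@pytest.fixture()
def clean_config():
    """No array effects, no noise, no planted effects: intensities are an
    exact function of the true abundances and fractions."""
    return em.SimulationConfig(n_mrna=40, n_lncrna=6, n_spikein=4, seed=2,
                               array_effect_sd=0.0, noise_log2_sd=0.0,
                               planted_effects=[])


@pytest.fixture()
def clean_dataset(clean_config):
    annotation, genes = em.generate_annotation(clean_config)
    arrays, truth = em.generate_intensities(clean_config, annotation)
    return {"config": clean_config, "annotation": annotation, "genes": genes,
            "arrays": arrays, "truth": truth}
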