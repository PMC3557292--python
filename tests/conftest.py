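import numpy as np
import pytest

import tilecall as tc


@pytest.fixture(scope="session")
def small_genome():
    return tc.random_genome(2000, 0.5, seed=101)


@pytest.fixture(scope="session")
def small_design(small_genome):
    return tc.build_tiling_design(small_genome, resolution=1, circular=True,
                                  genome_id="g2000")


@pytest.fixture(scope="session")
def true_model():
    return tc.sample_true_model(seed=202)


@pytest.fixture(scope="session")
def small_foldings(small_design):
    return tc.folding_energies(small_design.probe_codes())


@pytest.fixture(scope="session")
def noisefree_pair(small_genome, small_design, true_model, small_foldings):
    """Noise-free wt/mutant tables with one implanted substitution."""
    mutant, truth = tc.implant_substitutions(small_genome, 1, 300, seed=7)
    wt = tc.simulate_intensities(true_model, small_design, small_genome,
                                 small_foldings, 0.0, 1, sample_id="wt")
    mut = tc.simulate_intensities(true_model, small_design, mutant,
                                  small_foldings, 0.0, 2, sample_id="mut")
    return wt, mut, truth


def random_energy_model(rng):
    """A fully random (not realism-calibrated) model for oracle checks."""
    return tc.EnergyModel(
        eps_specific=rng.uniform(0.0, 2.0, 64),
        eps_nonspecific=rng.uniform(0.0, 1.0, 64),
        penalty=rng.uniform(0.0, 3.0, (64, 3)),
        weights=rng.uniform(0.0, 1.0, 19),
        alpha=rng.uniform(0.5, 1.5),
        intensity_scale=rng.uniform(500, 2000),
        background=rng.uniform(10, 100),
        conc_nonspecific=rng.uniform(0.005, 0.1),
    )
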