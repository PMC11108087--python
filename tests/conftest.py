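import numpy as np
import pytest

from codonmuse.genetic_code import amino_acid_mapping, build_standard_code
from codonmuse.model import ModelParameters, stationary_distribution
from codonmuse.simulate import _BASE_CATEGORY_PHI


@pytest.fixture(scope="session")
def code():
    return build_standard_code()


@pytest.fixture(scope="session")
def aa_mapping():
    return amino_acid_mapping()


@pytest.fixture
def rng():
    return np.random.default_rng(20240924)


def _base_phi(mapping, label):
    if label in _BASE_CATEGORY_PHI:
        return _BASE_CATEGORY_PHI[label]
    # split categories are labelled by their codon; inherit the family base
    return _BASE_CATEGORY_PHI[mapping.code.family_label(label)]


def realistic_params(mapping, rng, spread=0.15):
    """Model parameters scattered around the base fitness table."""
    phi = {
        l: float(_base_phi(mapping, l) * np.exp(spread * rng.standard_normal()))
        for l in mapping.free_labels
    }
    beta = {k: float(np.exp(spread * rng.standard_normal())) for k in "TCG"}
    return ModelParameters(mapping=mapping, beta=beta, phi=phi)


def simulate_counts(params, total, rng, species_id="sp"):
    from codonmuse.inference import CodonCounts

    psi = stationary_distribution(params)
    return CodonCounts(rng.multinomial(total, psi), species_id=species_id)
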