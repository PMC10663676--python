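import numpy as np
import pytest

from capsidkit import capsid_model as cm
from capsidkit import synthetic_data as sd


@pytest.fixture(scope="session")
def vp_species():
    return sd.default_vp_species()


@pytest.fixture(scope="session")
def scenarios():
    return sd.default_scenarios()


@pytest.fixture(scope="session")
def f11_spec(scenarios):
    return scenarios["f1_1"].ensemble


@pytest.fixture(scope="session")
def f22_spec(scenarios):
    return scenarios["f2_2"].ensemble


@pytest.fixture()
def toy_species():
    """Two synthetic species with round masses for hand arithmetic."""
    return (
        cm.VPSpecies(name="A", monomer_mass=60_000.0, epsilon214=1.0e6),
        cm.VPSpecies(name="B", monomer_mass=80_000.0, epsilon214=1.2e6),
    )


def make_ensemble(masses, fractions, genome_mass=0.0):
    species = tuple(
        cm.VPSpecies(name=f"S{i}", monomer_mass=float(m), epsilon214=1.0e6)
        for i, m in enumerate(masses)
    )
    return cm.CapsidEnsembleSpec(species, np.asarray(fractions, float), genome_mass)


@pytest.fixture(scope="session")
def ensemble_factory():
    return make_ensemble
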