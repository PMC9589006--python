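import warnings

import numpy as np
import pytest

from biliflux.community import AbundanceVector, CommunityOptions, DietSpec, build_community
from biliflux.gem_core import Metabolite, Reaction, StrainModel
from biliflux.synthetic import (
    COMMUNITY_BA_METABOLITES,
    FixtureBundle,
    default_fixture_set,
)

MASTER_SEED = 20221003


@pytest.fixture(scope="session")
def bundle() -> FixtureBundle:
    return default_fixture_set(MASTER_SEED)


@pytest.fixture(scope="session")
def community_options() -> CommunityOptions:
    return CommunityOptions(ba_metabolites=COMMUNITY_BA_METABOLITES)


@pytest.fixture(scope="session")
def uniform_community(bundle, community_options):
    ab = AbundanceVector(
        "uniform", {m.strain_id: 1.0 / len(bundle.strain_models) for m in bundle.strain_models}
    )
    return build_community(bundle.strain_models, ab, bundle.diet, community_options)


def make_chain_model(ab_upper=np.inf, uptake_lb=-10.0) -> StrainModel:
    """EX_A (uptake) -> A->B -> EX_B: the canonical 3-reaction chain."""
    return StrainModel(
        strain_id="chain",
        metabolites=[Metabolite("A[c]", "c"), Metabolite("B[c]", "c")],
        reactions=[
            Reaction("EX_A", {"A[c]": -1.0}, uptake_lb, 1000.0),
            Reaction("AB", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, ab_upper),
            Reaction("EX_B", {"B[c]": -1.0}, 0.0, 1000.0),
        ],
        biomass_reaction_id="AB",
        compartments={"c"},
    )


@pytest.fixture
def chain_model() -> StrainModel:
    return make_chain_model(ab_upper=1000.0)
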