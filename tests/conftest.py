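import numpy as np
import pytest

from ivgrass.design import enumerate_experiment
from ivgrass.simulator import SimConfig
from ivgrass.traits import TraitSpec


@pytest.fixture
def default_spec():
    return TraitSpec.default(cv=0.15)


@pytest.fixture
def high_iv_spec():
    return TraitSpec.default(cv=0.30)


@pytest.fixture
def small_config():
    """A fast short-season configuration for simulator unit tests."""
    return SimConfig(
        rows=8,
        cols=8,
        season_length=150,
        harvest_days=(60, 120),
    )


def make_design(
    trait_set="T3L",
    delta=0.0,
    cv=0.15,
    environment="N+",
    replicate=1,
    master_seed=123,
    pure=False,
):
    """One concrete CommunityDesign for simulator tests."""
    designs = enumerate_experiment(
        master_seed=master_seed,
        trait_sets=(trait_set,),
        deltas=(delta,),
        cv_levels=(cv,),
        environments=(environment,),
        replicates=replicate,
        include_pure=pure,
    )
    wanted = [d for d in designs if bool(d.pure_species) == pure]
    return wanted[-1]


@pytest.fixture
def mixture_design():
    return make_design()
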