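"""Shared fixtures: the synthetic congeneric-series library and target
database are built once per session (conformer generation dominates)."""

import pytest

from chempred.atc_classifier import ConsensusConfig
from chempred.compound_model import RawCompound, standardize
from chempred.fixtures import FixtureSpec, make_atc_library, make_target_db
from chempred.target_predictor import calibrate_background, curate

# Evaluation-scale conformer ensemble: the planted series are small, rigid
# molecules, so a handful of low-energy conformers per compound is enough to
# exercise the 3D method.
EVAL_CONFORMERS = 5


@pytest.fixture(scope="session")
def consensus_config():
    return ConsensusConfig(max_conformers=EVAL_CONFORMERS, atc_level=1)


@pytest.fixture(scope="session")
def atc_fixture(consensus_config):
    return make_atc_library(FixtureSpec(), consensus_config, with_conformers=True)


@pytest.fixture(scope="session")
def target_fixture():
    return make_target_db(FixtureSpec())


@pytest.fixture(scope="session")
def curation(target_fixture):
    return curate(target_fixture.records)


@pytest.fixture(scope="session")
def background(curation, target_fixture):
    return calibrate_background(curation.targets, target_fixture.decoys, seed=1)


def compound(smiles: str, source_id: str = "q"):
    return standardize(RawCompound(source_id=source_id, structure=smiles))


@pytest.fixture
def mk_compound():
    return compound
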