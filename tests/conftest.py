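import logging

import numpy as np
import pytest

from bbbgnn.encoder import EncoderConfig
from bbbgnn.heads import BBBModel, HeadConfig
from bbbgnn.molgraph import parse_smiles
from bbbgnn.synthdata import SynthConfig, generate_molecules

logging.getLogger("bbbgnn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale encoder: 3 layers, dim 16, no dropout (deterministic)."""
    return EncoderConfig(n_layers=3, dim=16, dropout=0.0)


@pytest.fixture()
def tiny_model(small_config):
    return BBBModel(["rat", "human"], small_config, HeadConfig(tag_dim=4, hidden=8),
                    seed=0)


@pytest.fixture(scope="session")
def random_graphs():
    """50 grammar-generated molecules parsed into graphs."""
    smiles = generate_molecules(SynthConfig(n_molecules=50, seed=123))
    return [parse_smiles(s) for s in smiles]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


# nine-molecule candidate panel: eight CNS ligands plus methane as the
# untargeted stand-in
LIGAND_PANEL = [
    ("acetylcholine", "CC(=O)OCC[N+](C)(C)C"),
    ("nicotine", "CN1CCC[C@H]1c1cccnc1"),
    ("tryptophan", "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O"),
    ("glucose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("dopamine", "NCCc1ccc(O)c(O)c1"),
    ("norepinephrine", "NC[C@H](O)c1ccc(O)c(O)c1"),
    ("serotonin", "NCCc1c[nH]c2ccc(O)cc12"),
    ("memantine", "CC12CC3CC(C)(C1)CC(N)(C3)C2"),
    ("methyl", "C"),
]
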