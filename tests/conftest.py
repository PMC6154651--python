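import pytest

from esterfunnel.chem_core import parse_smiles
from esterfunnel.enumeration import load_default_scaffold


@pytest.fixture(scope="session")
def oa_site():
    """Oleanolic-acid scaffold with its declared 3β-OH esterification site."""
    return load_default_scaffold()


@pytest.fixture(scope="session")
def acid_2a():
    """3-Phenylisoxazole-5-carboxylic acid, the archetypal building block."""
    return parse_smiles("OC(=O)c1cc(-c2ccccc2)no1", "phenylisoxazole_5_carboxylic")


# (smiles, name, hbd, hba, rotatable, rings, aromatic_rings) — counted by hand
# under the package conventions: HBD = H on N/O, HBA = N+O, rotatable =
# acyclic single bonds between non-terminal heavy atoms (amide C–N excluded),
# rings = SSSR.
HAND_COUNTED_PANEL = [
    ("CCO", "ethanol", 1, 1, 0, 0, 0),
    ("OC(=O)c1ccccc1", "benzoic_acid", 1, 2, 1, 1, 1),
    ("CC(=O)O", "acetic_acid", 1, 2, 0, 0, 0),
    ("CC(=O)NC", "n_methylacetamide", 1, 2, 0, 0, 0),
    ("c1ccccc1", "benzene", 0, 0, 0, 1, 1),
    ("C1CCCCC1", "cyclohexane", 0, 0, 0, 1, 0),
    ("c1ccc2ccccc2c1", "naphthalene", 0, 0, 0, 2, 2),
    ("CCOC(=O)C", "ethyl_acetate", 0, 2, 2, 0, 0),
    ("NCC(=O)O", "glycine", 3, 3, 1, 0, 0),
    ("Oc1ccccc1", "phenol", 1, 1, 0, 1, 1),
    ("CN(C)C=O", "dmf", 0, 2, 0, 0, 0),
    ("OC(=O)CCC(=O)O", "succinic_acid", 2, 4, 3, 0, 0),
    ("CC(C)=O", "acetone", 0, 1, 0, 0, 0),
    ("N#Cc1ccccc1", "benzonitrile", 0, 1, 1, 1, 1),
    ("OCC(O)CO", "glycerol", 3, 3, 2, 0, 0),
    ("CSSC", "dimethyl_disulfide", 0, 0, 1, 0, 0),
    ("c1ccncc1", "pyridine", 0, 1, 0, 1, 1),
    ("C1CC1", "cyclopropane", 0, 0, 0, 1, 0),
]
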