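import pytest

from rgcore import MoleculeRecord, RunConfig, assemble_rg
from rgcore.fixtures import demo_dataset, make_ambiguous_pair_series


@pytest.fixture(scope="session")
def config():
    return RunConfig(similarity_threshold=0.5, min_core_size=4)


@pytest.fixture(scope="session")
def toy_series():
    """Five benzamide analogues whose RGs share a 4-node common subgraph.

    At threshold 0.5 every molecule neighbours every other; at 0.7 four of
    them have three neighbours, so the extraction takes a different route
    to the same single core.
    """
    return [
        MoleculeRecord("A", "NC(=O)Cc1ccc(Cl)cc1", 5.0),
        MoleculeRecord("B", "NC(=O)Cc1ccc(Br)cc1", 5.5),
        MoleculeRecord("C", "CNC(=O)Cc1ccc(Cl)cc1", 6.0),
        MoleculeRecord("D", "NC(=O)Cc1ccc(Cl)c(F)c1", 6.5),
        MoleculeRecord("E", "CNC(=O)Cc1ccc(Cl)c(F)c1", 7.0),
    ]


@pytest.fixture(scope="session")
def toy_rgs(toy_series, config):
    return [assemble_rg(rec, config) for rec in toy_series]


@pytest.fixture(scope="session")
def many_records(config):
    """>=50 structurally varied molecules for invariant sweeps."""
    records = demo_dataset(seed=0)
    records += make_ambiguous_pair_series().records
    extra = [
        ("x-naphthalene", "c1ccc2ccccc2c1"),
        ("x-cyclohexanone", "O=C1CCCCC1"),
        ("x-acetylchloride", "CC(=O)Cl"),
        ("x-pyridine", "Cc1ccncc1"),
        ("x-phenol", "Oc1ccccc1"),
        ("x-indole", "c1ccc2[nH]ccc2c1"),
        ("x-sulfonamide", "CS(=O)(=O)Nc1ccccc1"),
        ("x-ester", "CCOC(=O)c1ccccc1"),
        ("x-urea", "NC(=O)Nc1ccccc1"),
        ("x-morpholine", "O1CCN(CC1)Cc1ccccc1"),
        ("x-tbu", "CC(C)(C)c1ccccc1"),
        ("x-nitrile", "N#Cc1ccc(O)cc1"),
    ]
    records += [MoleculeRecord(cid, smi, 5.0) for cid, smi in extra]
    assert len(records) >= 50
    return records


@pytest.fixture(scope="session")
def many_rgs(many_records, config):
    return [assemble_rg(rec, config) for rec in many_records]
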