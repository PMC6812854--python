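import pandas as pd
import pytest

from metanet.io import AnnotationTables, Dataset
from metanet.simulate import SimulationConfig, simulate_structure


@pytest.fixture
def toy_dataset() -> Dataset:
    """Two mesonetworks, three subnetworks, four enzymes with known ages.

    e1 (age 0.05) sits in s1 and s2 (both meso AAC); e2 (0.25) in s2;
    e3 (0.65) in s2 and s3 (s3 in CAR); e4 (0.95) in s3 only.
    """
    hierarchy = pd.DataFrame(
        {
            "map_id": ["map00001", "map00002", "map00003"],
            "map_name": ["glycolysis-like", "tca-like", "pentose-like"],
            "meso_code": ["AAC", "AAC", "CAR"],
        }
    )
    membership = pd.DataFrame(
        {
            "ec": ["1.1.1.1", "1.1.1.1", "2.2.2.2", "3.3.3.3", "3.3.3.3", "4.4.4.4"],
            "map_id": ["map00001", "map00002", "map00002", "map00002", "map00003", "map00003"],
        }
    )
    domains = pd.DataFrame(
        {
            "ec": ["1.1.1.1", "1.1.1.1", "2.2.2.2", "3.3.3.3", "4.4.4.4"],
            "scop_ccs": ["c.1.1.1", "d.2.1.1", "c.3.1.1", "b.4.1.1", "a.5.1.1"],
            "nd": [0.05, 0.30, 0.25, 0.65, 0.95],
        }
    )
    return Dataset(domains=domains, membership=membership, hierarchy=hierarchy)


@pytest.fixture
def toy_ages() -> dict[str, float]:
    # second-oldest rule applied to the toy domains
    return {"1.1.1.1": 0.30, "2.2.2.2": 0.25, "3.3.3.3": 0.65, "4.4.4.4": 0.95}


@pytest.fixture(scope="session")
def small_sim() -> Dataset:
    """A 300-enzyme seeded synthetic dataset shared across tests."""
    return simulate_structure(
        SimulationConfig(seed=11, n_enzymes=300, mean_subnets_per_meso=5)
    )


@pytest.fixture
def annotated_toy(toy_dataset: Dataset) -> Dataset:
    toy_dataset.annotations = AnnotationTables(
        taxa=pd.DataFrame(
            {
                "ec": ["1.1.1.1", "1.1.1.1", "2.2.2.2", "3.3.3.3"],
                "species": ["eco", "sce", "eco", "mja"],
                "superkingdom": ["B", "E", "B", "A"],
            }
        ),
        functions=pd.DataFrame(
            {
                "fsf_id": ["c.1.1", "d.2.1", "c.3.1", "b.4.1"],
                "general": ["Metabolism", "Regulation", "Metabolism", "Information"],
                "detailed": ["Metabolism.d1", "Regulation.d2", "Metabolism.d1", "Information.d3"],
            }
        ),
        catalysis=pd.DataFrame(
            {
                "ec": ["1.1.1.1", "1.1.1.1", "2.2.2.2"],
                "residue": ["D", "K", "S"],
                "role_group": ["nucleophile", "proton_shuttle", "nucleophile"],
            }
        ),
    )
    return toy_dataset
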