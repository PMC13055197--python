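import numpy as np
import pytest

import fernexpand as fx


@pytest.fixture(scope="session")
def balanced_tree():
    return fx.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def yule_tree_100():
    return fx.simulate_tree(100, seed=42)


@pytest.fixture(scope="session")
def default_climate():
    scenario = fx.SyntheticScenario(seed=11, n_species=1, n_zero_cep=0)
    return fx.simulate_climate_layers(scenario)


def make_records(species="sp", stage="sporophyte", coords=((0.0, 0.0),),
                 basis="PRESERVED_SPECIMEN", source="database"):
    return [
        fx.OccurrenceRecord(species_id=species, life_stage=stage,
                            longitude=lon, latitude=lat,
                            basis_of_record=basis, source=source)
        for lon, lat in coords
    ]
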