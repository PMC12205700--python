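import numpy as np
import pandas as pd
import pytest

from phytoind import CommunityScenario, generate_indicator_table, generate_releves


@pytest.fixture(scope="session")
def default_scenario():
    return CommunityScenario(seed=1)


@pytest.fixture(scope="session")
def synthetic_survey(default_scenario):
    """Default synthetic community + relevés + true labels (seed 1)."""
    com = generate_indicator_table(default_scenario, seed=1)
    rs, labels = generate_releves(default_scenario, com, seed=1)
    return com, rs, labels


@pytest.fixture
def tiny_indicator_csv(tmp_path):
    path = tmp_path / "indicators.csv"
    path.write_text(
        "species,Hd,fH,Rc,hemeroby_grade\n"
        "Phragmites australis,18,4,8,3\n"
        "Bromus tectorum,4,9,9,6\n"
        "Xanthium strumarium,9,7,7,5\n"
    )
    return path


@pytest.fixture
def tiny_releve_long_csv(tmp_path):
    path = tmp_path / "releves.csv"
    path.write_text(
        "plot_id,species,cover\n"
        "p1,Phragmites australis,60\n"
        "p1,Bromus tectorum,5\n"
        "p1,Xanthium strumarium,10\n"
        "p2,Bromus tectorum,25\n"
        "p2,Xanthium strumarium,2\n"
    )
    return path


@pytest.fixture
def two_block_releves():
    """Two disjoint species blocks of 10 plots each (unique CA split)."""
    rng = np.random.default_rng(7)
    plots = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
    species_a = [f"SpA{j}" for j in range(8)]
    species_b = [f"SpB{j}" for j in range(8)]
    covers = pd.DataFrame(np.nan, index=plots, columns=species_a + species_b)
    for i, p in enumerate(plots):
        block = species_a if p.startswith("a") else species_b
        chosen = rng.choice(len(block), size=5, replace=False)
        for j in chosen:
            covers.loc[p, block[j]] = float(rng.uniform(1, 50))
    covers.index.name = "plot_id"
    covers.columns.name = "species"
    from phytoind import ReleveSet

    return ReleveSet(covers)
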