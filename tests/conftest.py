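import random

import pytest
from rdkit import RDLogger

from scaforge import chem, datagen, oracles

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def cbd() -> chem.Molecule:
    return chem.canonicalize(chem.CBD_SMILES)


@pytest.fixture(scope="session")
def cbd_scaffold(cbd) -> chem.Molecule:
    return chem.murcko_scaffold(cbd)


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic scenario (seed 7), shared across the suite."""
    cfg = datagen.ScenarioConfig(seed=7)
    bundle, truth = datagen.generate_scenario(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def bundle_dir(scenario, tmp_path_factory):
    _, bundle, _ = scenario
    out = tmp_path_factory.mktemp("bundle")
    datagen.write_bundle(bundle, out)
    return out


@pytest.fixture(scope="session")
def molecule_pool(cbd, cbd_scaffold):
    """A diverse pool of valid molecules from the synthetic grammars."""
    rng = random.Random(11)
    pool = [cbd]
    from scaforge.ga import mutate

    for _ in range(60):
        m = cbd
        for _ in range(rng.randint(1, 3)):
            m = mutate(m, cbd_scaffold, rng)
        pool.append(m)
    for _ in range(60):
        m = datagen._decorate(rng.choice(datagen._DECOY_CORES), rng.randint(0, 4), rng)
        if m is not None:
            pool.append(m)
    return pool


@pytest.fixture(scope="session")
def convergence_oracle():
    spec = oracles.default_convergence_spec("T1")
    return spec, oracles.surrogate_docking(spec)
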