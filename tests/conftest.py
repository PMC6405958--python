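import pytest

import chemorg as co


@pytest.fixture(scope="session")
def model3():
    return co.load_fixture("model3")


@pytest.fixture(scope="session")
def model3b():
    return co.load_fixture("model3b")


@pytest.fixture(scope="session")
def model2():
    return co.load_fixture("model2")


@pytest.fixture(scope="session")
def model2b():
    return co.load_fixture("model2b")


@pytest.fixture(scope="session")
def model1():
    return co.load_fixture("model1")


@pytest.fixture(scope="session")
def model1b():
    return co.load_fixture("model1b")


def random_network(rng, max_species=8, max_reactions=12):
    """Random small mass-action network (for property tests)."""
    n_species = rng.integers(1, max_species + 1)
    species = [f"S{i}" for i in range(n_species)]
    n_rx = rng.integers(1, max_reactions + 1)
    lines = [f"species: {' '.join(species)}"]
    for k in range(n_rx):
        n_l = rng.integers(0, 3)
        n_r = rng.integers(0, 3)
        if n_l == 0 and n_r == 0:
            n_r = 1
        lhs = " + ".join(rng.choice(species) for _ in range(n_l))
        rhs = " + ".join(rng.choice(species) for _ in range(n_r))
        rate = float(rng.uniform(0.01, 2.0))
        lines.append(f"{lhs} -> {rhs} ; {rate:.4f} ; r{k + 1}")
    return co.parse_network("\n".join(lines))
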