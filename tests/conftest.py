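import numpy as np
import pytest

from pedigwas.pedigree import Individual, Pedigree
from pedigwas.simulate import SimConfig, simulate_pedigree


@pytest.fixture
def founder_pair():
    """Two unrelated founders."""
    return Pedigree([
        Individual("A", None, None, 1, 1900),
        Individual("B", None, None, 2, 1902),
    ])


@pytest.fixture
def nuclear_family():
    """Two founders with two full-sibling children."""
    return Pedigree([
        Individual("f", None, None, 1, 1900),
        Individual("m", None, None, 2, 1902),
        Individual("c1", "f", "m", 1, 1930),
        Individual("c2", "f", "m", 2, 1932),
    ])


@pytest.fixture
def three_generation_family():
    """Grandparents, two couples, full sibs, half sibs, cousins."""
    return Pedigree([
        Individual("gf", None, None, 1, 1900),
        Individual("gm", None, None, 2, 1900),
        Individual("u1", "gf", "gm", 1, 1925),   # two full-sib brothers
        Individual("u2", "gf", "gm", 1, 1927),
        Individual("w1", None, None, 2, 1926),
        Individual("w2", None, None, 2, 1928),
        Individual("w3", None, None, 2, 1930),
        Individual("k1", "u1", "w1", 1, 1950),   # child of u1 x w1
        Individual("k2", "u1", "w2", 2, 1952),   # half sib of k1
        Individual("k3", "u2", "w3", 1, 1954),   # full cousin of k1
    ])


@pytest.fixture
def half_first_cousins():
    """Half siblings whose children are half first cousins."""
    return Pedigree([
        Individual("g", None, None, 1, 1900),
        Individual("a1", None, None, 2, 1901),
        Individual("a2", None, None, 2, 1903),
        Individual("h1", "g", "a1", 1, 1925),    # half sibs h1, h2
        Individual("h2", "g", "a2", 2, 1927),
        Individual("s1", None, None, 2, 1926),
        Individual("s2", None, None, 1, 1928),
        Individual("c1", "h1", "s1", 1, 1950),   # half first cousins c1, c2
        Individual("c2", "s2", "h2", 2, 1952),
    ])


@pytest.fixture(scope="session")
def small_cohort():
    """A ~500-member simulated pedigree reused across tests."""
    cfg = SimConfig(n_founders=100, seed=42)
    return cfg, simulate_pedigree(cfg)


def random_pedigree(rng: np.random.Generator, n_founders: int = 8,
                    n_generations: int = 3) -> Pedigree:
    """Small random pedigree for property tests (allows consanguinity)."""
    inds = [Individual(f"F{i}", None, None, 1 + i % 2, 1900)
            for i in range(n_founders)]
    current = list(inds)
    counter = 0
    for gen in range(n_generations):
        males = [i for i in current if i.sex == 1]
        females = [i for i in current if i.sex == 2]
        rng.shuffle(males)
        rng.shuffle(females)
        nxt = []
        for m, f in zip(males, females):
            for _ in range(rng.integers(1, 4)):
                counter += 1
                nxt.append(Individual(f"G{gen}_{counter}", m.iid, f.iid,
                                      int(rng.integers(1, 3)),
                                      1900 + 25 * (gen + 1)))
        inds.extend(nxt)
        current = nxt
    return Pedigree(inds)
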