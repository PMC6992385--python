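import numpy as np
import pytest

from polcpm.energetics import ModelParams
from polcpm.engine import Simulation
from polcpm.hexgrid import build_lattice


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_lattice():
    return build_lattice(20, 20)


@pytest.fixture
def open_lattice():
    return build_lattice(10, 10, "open", "open")


def make_multicell_sim(n_cells=3, side=24, seed=7, **param_kw):
    """Small periodic simulation with a few compact cells (test workhorse)."""
    defaults = dict(kappa_A=0.3, kappa_P=0.2, eps0=12.0, delta_eps=4.0,
                    R=2, mu=0.1, B=1.5, delta_B=0.5, D=0.25)
    defaults.update(param_kw)
    params = ModelParams(**defaults)
    lat = build_lattice(side, side)
    sim = Simulation(lat, params, seed=seed, max_cells=n_cells + 8)
    rng = np.random.default_rng(seed)
    for _ in range(n_cells):
        for _attempt in range(50):
            center = int(rng.integers(lat.n_sites))
            try:
                sim.add_cell(center_site=center, area=int(rng.integers(8, 20)))
                break
            except ValueError:
                continue
    return sim


@pytest.fixture
def multicell_sim():
    return make_multicell_sim()


def random_blob(lattice, rng, area, forbidden=None):
    """A random connected site set grown by randomized BFS."""
    allowed = np.ones(lattice.n_sites, dtype=bool)
    if forbidden is not None:
        allowed &= ~forbidden
    start = int(rng.choice(np.flatnonzero(allowed)))
    blob = {start}
    frontier = [start]
    while len(blob) < area and frontier:
        cur = frontier[int(rng.integers(len(frontier)))]
        nbrs = [int(n) for n in lattice.neigh[cur]
                if n >= 0 and allowed[n] and int(n) not in blob]
        if not nbrs:
            frontier.remove(cur)
            continue
        nxt = nbrs[int(rng.integers(len(nbrs)))]
        blob.add(nxt)
        frontier.append(nxt)
    return sorted(blob)
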