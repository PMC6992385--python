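"""Three-state cell cycle (quiescent -> growth -> division) with contact inhibition.

Cells are quiescent by default; growth is arrested while the spread area
stays below the threshold A_T * A_ref (contact inhibition of
proliferation).  Once size fluctuations or tissue stretching push a cell
above the threshold it enters a deterministic growth state of duration Tg,
during which its effective contractility is lowered gradually so the
preferred area doubles (A* ~ eps0 / kappa_A, so kappa_A ramps linearly to
kappa_A/2; kappa_P follows as kappa_P * sqrt(kappa_A_eff / kappa_A) to keep
the perimeter energy per boundary event size-invariant).  A deterministic
division state of duration Td follows, with the polarizability set to zero
(mitotic rounding); at its end the cell splits across the plane through
its center of mass perpendicular to the gyration-tensor major axis, and
both daughters restart quiescent, unpolarized, with the mother's base
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hexgrid import ConfigurationError

__all__ = [
    "CycleParams",
    "QUIESCENT",
    "GROWTH",
    "DIVISION",
    "growth_contractility",
    "update_cycle",
    "divide_cell",
    "calibrate_reference_area",
]

QUIESCENT, GROWTH, DIVISION = 0, 1, 2


@dataclass
class CycleParams:
    """Cell-cycle timing and the contact-inhibition threshold.

    ``A_T`` is expressed in multiples of ``A_ref``, the equilibrium area of
    a solitary cell; ``stochastic_rate`` adds an optional per-MCS hazard of
    leaving quiescence regardless of size (default off), which desynchronizes
    the otherwise deterministic cycle.
    """
    enabled: bool = False
    Tg: int = 180
    Td: int = 20
    A_T: float = 1.0
    A_ref: float | None = None
    stochastic_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.Tg <= 0 or self.Td <= 0:
            raise ConfigurationError("Tg and Td must be > 0")
        if self.A_T <= 0:
            raise ConfigurationError("threshold A_T must be > 0")
        if self.stochastic_rate < 0:
            raise ConfigurationError("stochastic_rate must be >= 0")


def growth_contractility(base_kappa_A: float, base_kappa_P: float,
                         clock: int, Tg: int) -> tuple[float, float]:
    """Effective (kappa_A, kappa_P) at growth-phase clock in [0, Tg].

    kappa_A ramps linearly to kappa_A/2 (target area doubling);
    kappa_P scales with sqrt(kappa_A_eff / kappa_A).
    """
    if not 0 <= clock <= Tg:
        raise ValueError("growth clock out of range")
    frac = clock / Tg
    kA = base_kappa_A * (1.0 - 0.5 * frac)
    kP = base_kappa_P * np.sqrt(kA / base_kappa_A)
    return kA, kP


def update_cycle(sim) -> None:
    """Advance every living cell's cycle state by one MCS (called per MCS)."""
    cyc: CycleParams = sim.cycle
    if cyc.A_ref is None:
        raise ConfigurationError("cycle enabled but A_ref not set (calibrate first)")
    thresh = cyc.A_T * cyc.A_ref
    p = sim.params
    divided_any = False
    for cid in sim.config.cell_ids():
        ph = sim.phase[cid]
        if ph == QUIESCENT:
            if sim.config.area[cid] > thresh or (
                    cyc.stochastic_rate > 0 and sim.rng.random() < cyc.stochastic_rate):
                sim.phase[cid] = GROWTH
                sim.clock[cid] = 0
        elif ph == GROWTH:
            sim.clock[cid] += 1
            kA, kP = growth_contractility(p.kappa_A, p.kappa_P, int(sim.clock[cid]), cyc.Tg)
            sim.kA_eff[cid] = kA
            sim.kP_eff[cid] = kP
            if sim.clock[cid] >= cyc.Tg:
                sim.phase[cid] = DIVISION
                sim.clock[cid] = 0
                sim.deps_eff[cid] = 0.0  # mitotic rounding: polarizability to zero
        elif ph == DIVISION:
            sim.clock[cid] += 1
            if sim.clock[cid] >= cyc.Td:
                split = None
                if sim.config.area[cid] >= 2:
                    split = divide_cell(sim, int(cid))
                if split is not None:
                    divided_any = True
                else:
                    # too small or unsplittable: deferred one MCS
                    sim.clock[cid] = cyc.Td
    if divided_any:
        sim._pairs_dirty = True


def _components(sites: set[int], neigh: np.ndarray) -> list[set[int]]:
    remaining = set(sites)
    comps = []
    while remaining:
        seed = next(iter(remaining))
        comp = {seed}
        stack = [seed]
        remaining.discard(seed)
        while stack:
            cur = stack.pop()
            for n in neigh[cur]:
                n = int(n)
                if n in remaining:
                    remaining.discard(n)
                    comp.add(n)
                    stack.append(n)
        comps.append(comp)
    comps.sort(key=len, reverse=True)
    return comps


def divide_cell(sim, cell_id: int) -> tuple[int, int] | None:
    """Split a cell across its short axis into two connected daughters.

    Sites are partitioned by their projection onto the gyration-tensor
    major axis at the median (ties broken toward balancing areas);
    disconnected fragments are reassigned to the sister daughter.  Both
    daughters restart quiescent and unpolarized with the base parameters.
    Returns the two daughter ids, or None if no connected split was found
    (division deferred).
    """
    c = sim.config
    sites = c.sites_of(cell_id)
    if len(sites) < 2:
        return None
    xs = c.ux[sites] - c.ux[sites].mean()
    ys = c.uy[sites] - c.uy[sites].mean()
    cov = np.array([[np.mean(xs * xs), np.mean(xs * ys)],
                    [np.mean(xs * ys), np.mean(ys * ys)]])
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    proj = xs * major[0] + ys * major[1]
    order = np.argsort(proj, kind="stable")
    half = len(sites) // 2
    set_a = {int(s) for s in sites[order[:half]]}
    set_b = {int(s) for s in sites[order[half:]]}

    neigh = sim.lattice.neigh
    for _ in range(4):
        comps_a = _components(set_a, neigh)
        if len(comps_a) > 1:
            for comp in comps_a[1:]:
                set_a -= comp
                set_b |= comp
        comps_b = _components(set_b, neigh)
        if len(comps_b) > 1:
            for comp in comps_b[1:]:
                set_b -= comp
                set_a |= comp
        if len(_components(set_a, neigh)) == 1 and len(_components(set_b, neigh)) == 1:
            break
    else:
        return None
    if not set_a or not set_b:
        return None
    if len(_components(set_a, neigh)) != 1 or len(_components(set_b, neigh)) != 1:
        return None

    p = sim.params
    # daughter A keeps the mother's id; daughter B gets a fresh one
    new_id = c.new_cell_id()
    sim._sync_capacity()
    for s in set_b:
        c.owner[s] = new_id
    c.alive[new_id] = True
    for cid, sset in ((cell_id, set_a), (new_id, set_b)):
        idx = np.fromiter(sset, dtype=np.int64)
        c.area[cid] = len(idx)
        perim = 0
        for s in idx:
            for n in neigh[s]:
                if n >= 0 and c.owner[n] != cid:
                    perim += 1
        c.perim[cid] = perim
        c.comx[cid] = float(c.ux[idx].sum())
        c.comy[cid] = float(c.uy[idx].sum())
        sim.eps[idx] = p.eps0
        sim.F[idx] = 0
        sim.phase[cid] = QUIESCENT
        sim.clock[cid] = 0
        sim.kA_eff[cid] = p.kappa_A
        sim.kP_eff[cid] = p.kappa_P
        sim.deps_eff[cid] = p.delta_eps
    sim._pairs_dirty = True
    return cell_id, new_id


def calibrate_reference_area(params, T: int = 800, seed: int = 12345,
                             lattice_side: int | None = None) -> float:
    """Equilibrium area A_ref of a solitary cell, measured by simulation.

    Runs one unconfined cell for ``T`` MCS on a small periodic lattice and
    averages its area over the second half.
    """
    from .energetics import equilibrium_area
    from .engine import Simulation, place_single_cell
    from .hexgrid import build_lattice

    a_star = equilibrium_area(params)
    if lattice_side is None:
        lattice_side = int(max(24, 5 * np.sqrt(a_star)))
        lattice_side += lattice_side % 2
    lat = build_lattice(lattice_side, lattice_side)
    sim = Simulation(lat, params, seed=seed, max_cells=4)
    cid = place_single_cell(sim, area=a_star)
    sim.step(T // 2)
    areas = []
    for _ in range(T - T // 2):
        sim.step(1)
        areas.append(int(sim.config.area[cid]))
    return float(np.mean(areas))
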