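"""Event proposal, the Monte-Carlo-step loop, initialization, and run control.

A :class:`Simulation` bundles the lattice, the multicellular configuration,
the polarization/regulatory fields, the substrate field, and per-cell
effective parameters, and advances them by Monte Carlo steps (MCS).  One
MCS performs N_attempt propose/evaluate/accept cycles, where N_attempt is
the number of directed boundary pairs at the MCS start (all dynamics is
boundary-local, so the attempt budget tracks the interface size, making
the MCS timescale insensitive to empty-lattice size), then applies the
polarization update and, if enabled, the cell-cycle update.

Acceptance follows the canonical Metropolis rule min(1, exp(-dH/kBT)).
Because proposals are drawn from the state-dependent boundary-pair set,
plain Metropolis carries a small proposal-flux bias away from the
Boltzmann distribution at mu = 0; ``balanced_proposals=True`` adds the
Metropolis-Hastings correction (pair-count and channel-multiplicity
ratios) that makes feedback-free sampling exactly Boltzmann — used by the
equilibrium-sampling tests, and an O(1/P) effect for production-size cells.

Reproducibility: (seed, configuration) fully determines the trajectory.
The Monte Carlo kernel uses numba's process-global RNG; a Simulation seeds
it at construction, so interleaving `step` calls of two simulations breaks
determinism — run replicates sequentially (or call :meth:`Simulation.reseed`).
"""

from __future__ import annotations

import numpy as np

from . import _kernel
from .energetics import EventProposal, ModelParams
from .environment import SubstrateField
from .hexgrid import (EMPTY, WALL, SQRT3_2, CellConfiguration, ConfigurationError,
                      HexLattice, compact_blob, disk_offsets)

__all__ = [
    "Simulation",
    "TrajectoryRecorder",
    "TissueRecorder",
    "SnapshotRecorder",
    "place_single_cell",
    "place_cluster_on_disk",
    "place_confluent_strip",
]


class Simulation:
    """Mutable simulation state with seeded, reproducible MCS dynamics."""

    def __init__(self, lattice: HexLattice, params: ModelParams,
                 environment: SubstrateField | None = None,
                 cycle=None, seed: int = 0, max_cells: int = 64,
                 balanced_proposals: bool = False):
        self.lattice = lattice
        self.params = params
        self.cycle = cycle
        self.balanced_proposals = bool(balanced_proposals)

        self.config = CellConfiguration(lattice, max_cells=max_cells)
        N = lattice.n_sites
        self.eps = np.zeros(N)
        self.F = np.zeros(N, dtype=np.int64)
        self.phi = np.zeros(N)
        self.phi_mode = (_kernel.PHI_MULTIPLICATIVE
                         if params.phi_mode == "multiplicative" else _kernel.PHI_ADDITIVE)
        if environment is not None:
            if environment.lattice is not lattice:
                raise ConfigurationError("substrate field built for a different lattice")
            self.phi[:] = environment.phi
            self.config.owner[environment.forbidden] = WALL
        self.environment = environment

        n = len(self.config.area)
        self.kA_eff = np.full(n, params.kappa_A)
        self.kP_eff = np.full(n, params.kappa_P)
        self.deps_eff = np.full(n, params.delta_eps)
        self.phase = np.zeros(n, dtype=np.int64)      # 0 quiescent, 1 growth, 2 division
        self.clock = np.zeros(n, dtype=np.int64)

        self.offs_even, self.offs_odd = disk_offsets(int(params.R))
        self._pair_list = np.zeros(6 * N, dtype=np.int64)
        self._pair_pos = np.full(6 * N, -1, dtype=np.int64)
        self._n_pairs = 0
        self._pairs_dirty = True
        self._visited = np.zeros(N, dtype=np.int64)
        self._stamp = np.zeros(1, dtype=np.int64)
        self._queue = np.zeros(N, dtype=np.int64)

        self.mcs = 0
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        self.rng = np.random.default_rng(ss)
        self._kernel_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        self.reseed()

    # -- plumbing ----------------------------------------------------------

    def reseed(self) -> None:
        """(Re)seed the Monte Carlo kernel RNG for this simulation."""
        _kernel.seed_rng(self._kernel_seed + self.mcs)

    def _sync_capacity(self) -> None:
        n = len(self.config.area)
        m = len(self.kA_eff)
        if n <= m:
            return
        pad = n - m
        p = self.params
        self.kA_eff = np.concatenate([self.kA_eff, np.full(pad, p.kappa_A)])
        self.kP_eff = np.concatenate([self.kP_eff, np.full(pad, p.kappa_P)])
        self.deps_eff = np.concatenate([self.deps_eff, np.full(pad, p.delta_eps)])
        self.phase = np.concatenate([self.phase, np.zeros(pad, dtype=np.int64)])
        self.clock = np.concatenate([self.clock, np.zeros(pad, dtype=np.int64)])

    def _ensure_pairs(self) -> None:
        if self._pairs_dirty:
            self._n_pairs = _kernel.rebuild_pairs(self.config.owner, self.lattice.neigh,
                                                  self._pair_list, self._pair_pos)
            self._pairs_dirty = False

    @property
    def n_boundary_pairs(self) -> int:
        self._ensure_pairs()
        return int(self._n_pairs)

    # -- initialization ----------------------------------------------------

    def add_cell(self, sites=None, center_site: int | None = None,
                 area: int | None = None) -> int:
        """Seed one cell: explicit site set, or a compact blob of given area.

        The cell starts unpolarized (eps = eps0 everywhere, F = 0) and
        quiescent.
        """
        if sites is None:
            if center_site is None or area is None:
                raise ConfigurationError("give either sites or (center_site, area)")
            allowed = self.config.owner == EMPTY
            sites = compact_blob(self.lattice, int(center_site), int(area), allowed)
        cid = self.config.add_cell(sites)
        self._sync_capacity()
        idx = np.asarray(sites, dtype=np.int64)
        self.eps[idx] = self.params.eps0
        self.F[idx] = 0
        self.phase[cid] = 0
        self.clock[cid] = 0
        self._pairs_dirty = True
        return cid

    def remove_walls(self) -> None:
        """Turn every forbidden wall site into free substrate."""
        wall = self.config.owner == WALL
        self.config.owner[wall] = EMPTY
        self.phi[wall] = 0.0
        self._pairs_dirty = True

    # -- dynamics ----------------------------------------------------------

    def step(self, n_mcs: int = 1) -> None:
        """Advance ``n_mcs`` Monte Carlo steps (cycle update interleaved per MCS)."""
        from . import proliferation
        cyc = self.cycle is not None and getattr(self.cycle, "enabled", False)
        done = 0
        while done < n_mcs:
            chunk = 1 if cyc else (n_mcs - done)
            self._ensure_pairs()
            lat = self.lattice
            self._n_pairs = _kernel.run_mcs(
                chunk,
                self.config.owner, self.eps, self.F, self.phi, self.phi_mode,
                lat.neigh, lat.cx, lat.cy, lat.width, lat.height,
                1 if lat.boundary_x == "periodic" else 0,
                1 if lat.boundary_y == "periodic" else 0,
                self.config.ux, self.config.uy,
                self.config.area, self.config.perim,
                self.config.comx, self.config.comy,
                self.kA_eff, self.kP_eff, self.deps_eff,
                self.params.eps0, self.params.mu,
                self.params.B, self.params.delta_B, self.params.D,
                1 if self.params.friction_mode == "per_edge" else 0,
                self.params.kBT, 1 if self.balanced_proposals else 0,
                self.offs_even, self.offs_odd, lat.n_cols, lat.n_rows,
                self._pair_list, self._pair_pos, self._n_pairs,
                self._visited, self._stamp, self._queue)
            self.mcs += chunk
            done += chunk
            if cyc:
                proliferation.update_cycle(self)

    def run(self, n_mcs: int, recorders=(), events=()) -> None:
        """Run ``n_mcs`` MCS, invoking recorders at their intervals.

        ``events`` is a sequence of ``(mcs_time, callable)`` pairs executed
        when the counter reaches that absolute time (e.g. wall removal).
        Recorders fire at t % interval == 0, including at the start.
        """
        events = sorted(events, key=lambda e: e[0])
        for rec in recorders:
            if self.mcs % rec.interval == 0:
                rec.record(self)
        end = self.mcs + n_mcs
        while self.mcs < end:
            nxt = end
            for t_ev, _fn in events:
                if t_ev > self.mcs:
                    nxt = min(nxt, t_ev)
                    break
            for rec in recorders:
                k = rec.interval
                nxt = min(nxt, (self.mcs // k + 1) * k)
            self.step(nxt - self.mcs)
            for t_ev, fn in events:
                if t_ev == self.mcs:
                    fn(self)
            for rec in recorders:
                if self.mcs % rec.interval == 0:
                    rec.record(self)

    # -- single-event interface (tests, inspection) ------------------------

    def propose_event(self, rng: np.random.Generator | None = None) -> EventProposal:
        """Draw one event uniformly from the live directed boundary-pair set."""
        self._ensure_pairs()
        if self._n_pairs == 0:
            raise RuntimeError("no boundary pairs: empty or frozen system")
        rng = self.rng if rng is None else rng
        pid = int(self._pair_list[rng.integers(self._n_pairs)])
        a, d = pid // 6, pid % 6
        b = int(self.lattice.neigh[a, d])
        return EventProposal.classify(int(self.config.owner[a]),
                                      int(self.config.owner[b]), a, b)

    def enumerate_pairs(self) -> list[tuple[int, int]]:
        """All directed boundary pairs (source, target), recomputed from scratch."""
        out = []
        owner = self.config.owner
        for a in range(self.lattice.n_sites):
            if owner[a] == WALL:
                continue
            for b in self.lattice.neigh[a]:
                if b >= 0 and owner[b] != WALL and owner[a] != owner[b]:
                    out.append((a, int(b)))
        return out

    def event_delta_H(self, source_site: int, target_site: int) -> float:
        """Incremental event energy (Hamiltonian + friction/substrate terms)."""
        g = self.config.owner[source_site]
        l = self.config.owner[target_site]
        EventProposal.classify(int(g), int(l), source_site, target_site)  # validates
        dH = _kernel.eval_event(
            self.config.owner, self.eps, self.phi, self.phi_mode,
            self.lattice.neigh, self.config.area, self.config.perim,
            self.kA_eff, self.kP_eff,
            self.params.B, self.params.delta_B, self.params.D,
            1 if self.params.friction_mode == "per_edge" else 0,
            source_site, target_site)[0]
        return float(dH)

    def apply_event(self, source_site: int, target_site: int) -> None:
        """Apply a flip through the cached-update path (no feedback recording)."""
        g = int(self.config.owner[source_site])
        l = int(self.config.owner[target_site])
        EventProposal.classify(g, l, source_site, target_site)
        if l > 0:
            self.config.remove_site(l, target_site)
        if g > 0:
            self.config.add_site(g, target_site, source_site)
            self.eps[target_site] = self.eps[source_site]
        else:
            self.eps[target_site] = 0.0
        self.F[target_site] = 0
        self._pairs_dirty = True

    # -- energies ----------------------------------------------------------

    def contact_edges(self) -> int:
        """Number of undirected cell-cell contact edges (heterotypic)."""
        owner = self.config.owner
        count = 0
        for d in range(3):  # E, NE, NW: each undirected edge counted once
            nb = self.lattice.neigh[:, d]
            ok = nb >= 0
            a_own = owner[ok]
            b_own = owner[nb[ok]]
            count += int(np.sum((a_own > 0) & (b_own > 0) & (a_own != b_own)))
        return count

    def total_energy(self) -> float:
        """Full effective energy recomputed from scratch (correctness oracle)."""
        from .hexgrid import EDGE_LENGTH
        H = 0.0
        for cid in self.config.cell_ids():
            A = float(self.config.area[cid])
            P = float(self.config.perim[cid]) * EDGE_LENGTH
            H += self.kA_eff[cid] * A * A + self.kP_eff[cid] * P * P
        occ = self.config.owner > 0
        if self.phi_mode == _kernel.PHI_MULTIPLICATIVE:
            H -= float(np.sum(self.eps[occ] * self.phi[occ]))
        else:
            H -= float(np.sum(self.eps[occ] + self.phi[occ]))
        H -= self.params.B * self.contact_edges()
        return H

    # -- invariant checks --------------------------------------------------

    def debug_check(self) -> None:
        """Assert cache, accounting, polarization-bound, and wall invariants."""
        from .polarity import polarization_bounds_ok
        self.config.check_caches()
        assert self.config.site_accounting_ok(), "site accounting broken"
        occ = self.config.owner > 0
        if self.environment is not None:
            assert not np.any(occ & self.environment.forbidden), "cell on forbidden site"
        lo, hi = self.params.eps_min, self.params.eps_max
        assert polarization_bounds_ok(self.eps, self.config.owner, self.params), \
            f"eps outside [{lo}, {hi}]"


# ---------------------------------------------------------------------------
# Placement helpers
# ---------------------------------------------------------------------------

def place_single_cell(sim: Simulation, area: int, center_site: int | None = None) -> int:
    """One compact unpolarized cell in the middle of the lattice."""
    if center_site is None:
        lat = sim.lattice
        center_site = lat.site_index(lat.n_cols // 2, lat.n_rows // 2)
    return sim.add_cell(center_site=center_site, area=area)


def place_cluster_on_disk(sim: Simulation, n_cells: int, cell_area: int,
                          r0: float, center: tuple[float, float] | None = None) -> list[int]:
    """Seed ``n_cells`` compact cells evenly spaced on a ring inside a disk pattern."""
    lat = sim.lattice
    if center is None:
        center = (lat.width / 2.0, lat.height / 2.0)
    radius = 0.45 * r0
    ids = []
    for k in range(n_cells):
        th = 2 * np.pi * k / n_cells
        x = center[0] + radius * np.cos(th)
        y = center[1] + radius * np.sin(th)
        site = int(np.argmin((lat.cx - x) ** 2 + (lat.cy - y) ** 2))
        ids.append(sim.add_cell(center_site=site, area=cell_area))
    return ids


def place_confluent_strip(sim: Simulation, x_left: float, x_right: float,
                          cell_area: int) -> list[int]:
    """Tile the admissible band with a confluent sheet of compact cells.

    Cell seeds sit on a triangular grid sized so each cell gets about
    ``cell_area`` sites; every admissible site is assigned to its nearest
    seed (periodic in y), stray disconnected fragments are attached to
    adjacent cells.  This prepares the pre-grown confluent state directly
    instead of simulating the slow growth to confluence.
    """
    lat = sim.lattice
    owner = sim.config.owner
    admissible = (owner == EMPTY) & (lat.cx >= x_left) & (lat.cx <= x_right)
    a_cart = cell_area * SQRT3_2
    s = np.sqrt(2.0 * a_cart / np.sqrt(3.0))
    n_rows = max(1, int(round(lat.height / (s * SQRT3_2))))
    dy = lat.height / n_rows
    width = x_right - x_left
    n_per_row = max(1, int(round(width / s)))
    dx = width / n_per_row
    centers = []
    for j in range(n_rows):
        off = 0.5 * dx if (j % 2) else 0.0
        for i in range(n_per_row):
            centers.append((x_left + (i + 0.25) * dx + off, (j + 0.5) * dy))
    centers = np.array(centers)
    sites = np.flatnonzero(admissible)
    ddx = sites[:, None] * 0.0 + (lat.cx[sites][:, None] - centers[None, :, 0])
    ddy = lat.cy[sites][:, None] - centers[None, :, 1]
    if lat.boundary_y == "periodic":
        ddy -= lat.height * np.round(ddy / lat.height)
    if lat.boundary_x == "periodic":
        ddx -= lat.width * np.round(ddx / lat.width)
    label = np.argmin(ddx * ddx + ddy * ddy, axis=1)

    neigh = lat.neigh
    ids = []
    orphan_sites: list[int] = []
    lab_of = {int(s_): int(l_) for s_, l_ in zip(sites, label)}
    for k in range(len(centers)):
        group = [int(s_) for s_ in sites[label == k]]
        if not group:
            continue
        # connected components within the group
        remaining = set(group)
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
        ids.append(sim.add_cell(sorted(comps[0])))
        for comp in comps[1:]:
            orphan_sites.extend(comp)
    # attach stray fragments to adjacent cells
    pending = list(orphan_sites)
    while pending:
        progressed = False
        nxt = []
        for s_ in pending:
            attached = False
            for n in neigh[s_]:
                if n >= 0 and sim.config.owner[n] > 0:
                    cid = int(sim.config.owner[n])
                    sim.config.add_site(cid, s_, int(n))
                    sim.eps[s_] = sim.params.eps0
                    attached = True
                    progressed = True
                    break
            if not attached:
                nxt.append(s_)
        if not progressed:
            break
        pending = nxt
    sim._pairs_dirty = True
    del lab_of
    return ids


# ---------------------------------------------------------------------------
# Recorders
# ---------------------------------------------------------------------------

def _pad_stack(rows: list[np.ndarray], fill=np.nan) -> np.ndarray:
    width = max(len(r) for r in rows)
    out = np.full((len(rows), width), fill, dtype=float)
    for i, r in enumerate(rows):
        out[i, :len(r)] = r
    return out


class TrajectoryRecorder:
    """Per-cell center-of-mass / area / perimeter time series at a fixed interval."""

    def __init__(self, interval: int = 1):
        if interval < 1:
            raise ConfigurationError("recorder interval must be >= 1")
        self.interval = int(interval)
        self.times: list[int] = []
        self._comx: list[np.ndarray] = []
        self._comy: list[np.ndarray] = []
        self._area: list[np.ndarray] = []
        self._perim: list[np.ndarray] = []

    def record(self, sim: Simulation) -> None:
        c = sim.config
        a = c.area.astype(float).copy()
        a[~c.alive] = np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            self._comx.append(c.comx / a)
            self._comy.append(c.comy / a)
        self._area.append(a)
        p = c.perim.astype(float).copy()
        p[~c.alive] = np.nan
        self._perim.append(p)
        self.times.append(sim.mcs)

    def arrays(self) -> dict:
        """Stacked arrays: t (T,), com (T, C, 2), area (T, C), perim (T, C).

        Column 0 is the unused cell id 0; dead/not-yet-born cells are NaN.
        """
        return {
            "t": np.asarray(self.times, dtype=float),
            "com": np.dstack([_pad_stack(self._comx), _pad_stack(self._comy)]),
            "area": _pad_stack(self._area),
            "perim": _pad_stack(self._perim),
        }


class SnapshotRecorder:
    """Full owner/eps lattice snapshots (in memory)."""

    def __init__(self, interval: int):
        self.interval = int(interval)
        self.times: list[int] = []
        self.owners: list[np.ndarray] = []
        self.eps: list[np.ndarray] = []

    def record(self, sim: Simulation) -> None:
        self.times.append(sim.mcs)
        self.owners.append(sim.config.owner.copy())
        self.eps.append(sim.eps.copy())


class TissueRecorder:
    """Space-time profiles of an expanding strip: density, stress, velocity, fronts.

    Profiles are y-averaged into x-bins at every interval; per-cell
    velocities come from center-of-mass displacement between consecutive
    records.
    """

    def __init__(self, interval: int, x_edges: np.ndarray):
        from . import observables  # deferred: observables imports nothing from engine
        self._obs = observables
        self.interval = int(interval)
        self.x_edges = np.asarray(x_edges, dtype=float)
        self.times: list[int] = []
        self.density: list[np.ndarray] = []
        self.sigma_xx: list[np.ndarray] = []
        self.vx: list[np.ndarray] = []
        self.n_cells: list[int] = []
        self.total_cell_area: list[int] = []
        self.extent: list[tuple[float, float]] = []
        self.front_right: list[np.ndarray] = []
        self.front_left: list[np.ndarray] = []
        self._prev_comx: np.ndarray | None = None
        self._prev_t: int | None = None
        self._height: float | None = None

    def record(self, sim: Simulation) -> None:
        obs = self._obs
        lat = sim.lattice
        self._height = lat.height
        c = sim.config
        owner = c.owner
        occ = owner > 0
        ncap = len(c.area)
        a = c.area.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            comx = np.where(c.alive, c.comx / np.where(a > 0, a, 1), np.nan)
        pi = obs.cell_pressure(a, c.perim.astype(float),
                               np.full(ncap, sim.params.eps0),
                               sim.kA_eff[:ncap], sim.kP_eff[:ncap])
        if self._prev_comx is not None:
            dt = sim.mcs - self._prev_t
            prev = self._prev_comx
            if len(prev) < ncap:
                prev = np.concatenate([prev, np.full(ncap - len(prev), np.nan)])
            vxc = (comx - prev) / max(dt, 1)
        else:
            vxc = np.full(ncap, np.nan)
        self.times.append(sim.mcs)
        self.density.append(obs.density_profile(lat, owner, self.x_edges))
        self.sigma_xx.append(obs.stress_profile(lat, owner, self.x_edges, pi))
        self.vx.append(obs.velocity_profile(lat, owner, self.x_edges, vxc))
        self.n_cells.append(int(np.sum(c.alive)))
        self.total_cell_area.append(int(c.area[c.alive].sum()))
        if np.any(occ):
            self.extent.append((float(lat.cx[occ].min()), float(lat.cx[occ].max())))
        else:
            self.extent.append((np.nan, np.nan))
        self.front_right.append(obs.front_profile(lat, owner, "right"))
        self.front_left.append(obs.front_profile(lat, owner, "left"))
        self._prev_comx = comx
        self._prev_t = sim.mcs

    def kymographs(self):
        from .observables import Kymograph
        return Kymograph(
            x_edges=self.x_edges,
            times=np.asarray(self.times, dtype=float),
            density=np.vstack(self.density),
            sigma_xx=np.vstack(self.sigma_xx),
            vx=np.vstack(self.vx),
        )

    def mean_density(self) -> np.ndarray:
        """Cells per unit Cartesian area of the currently colonized band."""
        h = self._height if self._height else 1.0
        out = []
        for n, (x0, x1) in zip(self.n_cells, self.extent):
            width = max(x1 - x0, 1.0)
            out.append(n / (width * h))
        return np.asarray(out, dtype=float)
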