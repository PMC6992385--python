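"""Hexagonal lattice geometry and the multicellular configuration state.

The substrate is tessellated into a honeycomb lattice of unit lattice
constant; every site is one discrete cell-substrate adhesion patch.  Sites
are stored in "odd-r offset" coordinates (pointy-top hexagons): site
``(q, r)`` sits at Cartesian ``x = q + 0.5*(r odd)``, ``y = (sqrt(3)/2) r``.
With an even number of rows this makes the periodic cell rectangular, so
vertical wall strips remain straight across the periodic-y seam.

Cells are contiguous sets of sites.  :class:`CellConfiguration` keeps the
owner map plus incrementally maintained caches (area = site count,
perimeter = boundary-edge count, center-of-mass sums over *unwrapped*
Cartesian coordinates so trajectories stay continuous across periodic
images).  Every incremental update has a from-scratch recount counterpart
used as a correctness oracle.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EMPTY",
    "WALL",
    "SQRT3_2",
    "EDGE_LENGTH",
    "EDGE_DX",
    "EDGE_DY",
    "HexLattice",
    "CellConfiguration",
    "build_lattice",
    "disk_offsets",
    "hex_disk_size",
    "move_preserves_connectivity",
]

EMPTY = 0   # owner id of unoccupied substrate
WALL = -1   # owner id of forbidden (no-adhesion) sites

SQRT3_2 = np.sqrt(3.0) / 2.0
# Side length of one hexagon at unit lattice constant (center spacing): each
# boundary edge of a cell contributes this much physical contour length.
EDGE_LENGTH = 1.0 / np.sqrt(3.0)

# Direction order (counter-clockwise): E, NE, NW, W, SW, SE.
# The reverse of direction d is (d + 3) % 6 for both row parities.
EDGE_DX = np.array([1.0, 0.5, -0.5, -1.0, -0.5, 0.5])
EDGE_DY = np.array([0.0, SQRT3_2, SQRT3_2, 0.0, -SQRT3_2, -SQRT3_2])

# (dq, dr) neighbor offsets for even / odd rows (odd-r offset layout).
_OFFS_EVEN = np.array([(1, 0), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1)], dtype=np.int64)
_OFFS_ODD = np.array([(1, 0), (1, 1), (0, 1), (-1, 0), (0, -1), (1, -1)], dtype=np.int64)


class ConfigurationError(ValueError):
    """Invalid geometry or parameter specification."""


def hex_disk_size(R: int) -> int:
    """Number of sites within hex graph distance ``R`` on an unbounded lattice."""
    return 1 + 3 * R * (R + 1)


def _axial_to_offset_q(aq: int, r: int) -> int:
    return aq + (r - (r & 1)) // 2


def disk_offsets(R: int) -> tuple[np.ndarray, np.ndarray]:
    """Offset-coordinate deltas of the hex disk of radius ``R``.

    Returns ``(offs_even, offs_odd)``, each of shape ``(1 + 3R(R+1), 2)``
    holding ``(dq, dr)`` for centers on even and odd rows respectively.
    """
    if R < 0:
        raise ConfigurationError("signaling radius R must be >= 0")
    deltas = []
    for ar in range(-R, R + 1):
        for aq in range(max(-R, -R - ar), min(R, R - ar) + 1):
            deltas.append((aq, ar))
    out = []
    for parity in (0, 1):
        rows = []
        for aq, ar in deltas:
            rt = parity + ar
            qt = _axial_to_offset_q(aq, rt)
            # center (0, parity) has offset q = 0 for both parities
            rows.append((qt, ar))
        out.append(np.array(rows, dtype=np.int64))
    return out[0], out[1]


class HexLattice:
    """Honeycomb lattice with O(1) neighbor queries.

    Parameters
    ----------
    n_cols, n_rows
        Axial extents; total site count is ``n_cols * n_rows``.
    boundary_x, boundary_y
        Either ``"periodic"`` or ``"open"``.  Under periodic-y an even
        ``n_rows`` keeps the Cartesian embedding consistent across the
        seam; odd values are allowed but give a twisted (degenerate)
        embedding.
    """

    def __init__(self, n_cols: int, n_rows: int,
                 boundary_x: str = "periodic", boundary_y: str = "periodic"):
        if n_cols < 1 or n_rows < 1:
            raise ConfigurationError("lattice dimensions must be >= 1")
        if boundary_x not in ("periodic", "open") or boundary_y not in ("periodic", "open"):
            raise ConfigurationError("boundary must be 'periodic' or 'open'")
        self.n_cols = int(n_cols)
        self.n_rows = int(n_rows)
        self.boundary_x = boundary_x
        self.boundary_y = boundary_y
        self.n_sites = self.n_cols * self.n_rows

        q = np.arange(self.n_sites) % self.n_cols
        r = np.arange(self.n_sites) // self.n_cols
        self.q = q.astype(np.int64)
        self.r = r.astype(np.int64)
        self.cx = q + 0.5 * (r & 1)
        self.cy = SQRT3_2 * r
        # Cartesian periods (meaningful under periodic boundaries)
        self.width = float(self.n_cols)
        self.height = SQRT3_2 * self.n_rows

        self.neigh = self._build_neighbor_table()

    def _build_neighbor_table(self) -> np.ndarray:
        nc, nr = self.n_cols, self.n_rows
        neigh = np.full((self.n_sites, 6), -1, dtype=np.int64)
        for parity, offs in ((0, _OFFS_EVEN), (1, _OFFS_ODD)):
            rows = np.arange(parity, nr, 2)
            if rows.size == 0:
                continue
            qq, rr = np.meshgrid(np.arange(nc), rows, indexing="ij")
            base = (rr * nc + qq).ravel()
            for d in range(6):
                qt = qq.ravel() + offs[d, 0]
                rt = rr.ravel() + offs[d, 1]
                ok = np.ones_like(qt, dtype=bool)
                if self.boundary_x == "periodic":
                    qt = qt % nc
                else:
                    ok &= (qt >= 0) & (qt < nc)
                if self.boundary_y == "periodic":
                    rt = rt % nr
                else:
                    ok &= (rt >= 0) & (rt < nr)
                tgt = np.where(ok, rt % nr * nc + qt % nc, -1)
                neigh[base, d] = tgt
        return neigh

    # -- queries -----------------------------------------------------------

    def site_index(self, q: int, r: int) -> int:
        if not (0 <= q < self.n_cols and 0 <= r < self.n_rows):
            raise ConfigurationError(f"site ({q}, {r}) off lattice")
        return r * self.n_cols + q

    def site_qr(self, site: int) -> tuple[int, int]:
        self._check_site(site)
        return int(self.q[site]), int(self.r[site])

    def _check_site(self, site: int) -> None:
        if not (0 <= site < self.n_sites):
            raise ConfigurationError(f"site {site} off lattice")

    def neighbors(self, site: int) -> np.ndarray:
        """Existing neighbors of ``site`` in fixed CCW order (E, NE, NW, W, SW, SE)."""
        self._check_site(site)
        n = self.neigh[site]
        return n[n >= 0]

    def disk_neighborhood(self, site: int, R: int) -> np.ndarray:
        """All sites with hex graph distance <= R from ``site`` (wrapped or clipped)."""
        self._check_site(site)
        offs_even, offs_odd = disk_offsets(R)
        q0, r0 = int(self.q[site]), int(self.r[site])
        offs = offs_odd if (r0 & 1) else offs_even
        qt = q0 + offs[:, 0]
        rt = r0 + offs[:, 1]
        ok = np.ones(len(offs), dtype=bool)
        if self.boundary_x == "periodic":
            qt = qt % self.n_cols
        else:
            ok &= (qt >= 0) & (qt < self.n_cols)
        if self.boundary_y == "periodic":
            rt = rt % self.n_rows
        else:
            ok &= (rt >= 0) & (rt < self.n_rows)
        sites = (rt % self.n_rows) * self.n_cols + (qt % self.n_cols)
        return np.unique(sites[ok])

    def wrap_delta(self, dx: float, dy: float) -> tuple[float, float]:
        """Minimum-image Cartesian displacement."""
        if self.boundary_x == "periodic":
            dx -= self.width * np.round(dx / self.width)
        if self.boundary_y == "periodic":
            dy -= self.height * np.round(dy / self.height)
        return dx, dy

    def __repr__(self) -> str:  # pragma: no cover
        return (f"HexLattice({self.n_cols}x{self.n_rows}, "
                f"x={self.boundary_x}, y={self.boundary_y})")


def build_lattice(n_cols: int, n_rows: int,
                  boundary_x: str = "periodic", boundary_y: str = "periodic") -> HexLattice:
    """Construct a :class:`HexLattice` (thin named constructor)."""
    return HexLattice(n_cols, n_rows, boundary_x, boundary_y)


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def _ring_arcs(owner: np.ndarray, neigh: np.ndarray, cell_id: int, site: int) -> int:
    """Number of contiguous arcs of cell-owned neighbors around ``site``.

    Off-lattice neighbors count as not owned.  One arc (or zero) means the
    local neighborhood stays connected if ``site`` is removed.
    """
    owned = [(0 <= n) and owner[n] == cell_id for n in neigh[site]]
    arcs = 0
    for d in range(6):
        if owned[d] and not owned[d - 1]:
            arcs += 1
    return arcs


def _cell_connected_without(owner: np.ndarray, neigh: np.ndarray,
                            cell_id: int, site: int, area: int) -> bool:
    """Flood fill over the cell's sites excluding ``site``; True if one component."""
    starts = [n for n in neigh[site] if n >= 0 and owner[n] == cell_id]
    if not starts:
        return area <= 1
    seen = {site}  # excluded
    stack = [starts[0]]
    seen.add(starts[0])
    count = 1
    while stack:
        cur = stack.pop()
        for n in neigh[cur]:
            if n >= 0 and n not in seen and owner[n] == cell_id:
                seen.add(n)
                count += 1
                stack.append(n)
    return count == area - 1


def move_preserves_connectivity(config: "CellConfiguration", cell_id: int, site: int) -> bool:
    """Would the cell stay connected (6-neighborhood) after losing ``site``?

    Fast local ring check; falls back to a flood fill when the ring is
    ambiguous (more than one arc of owned neighbors).
    """
    if config.owner[site] != cell_id:
        raise ValueError(f"site {site} not owned by cell {cell_id}")
    arcs = _ring_arcs(config.owner, config.lattice.neigh, cell_id, site)
    if arcs <= 1:
        return True
    return _cell_connected_without(config.owner, config.lattice.neigh,
                                   cell_id, site, int(config.area[cell_id]))


# ---------------------------------------------------------------------------
# Multicellular configuration
# ---------------------------------------------------------------------------

class CellConfiguration:
    """Owner map plus cached per-cell geometry.

    ``owner[site]`` is 0 (empty), -1 (forbidden wall), or a positive cell
    id.  Caches: ``area`` (site count), ``perim`` (number of lattice edges
    with exactly one endpoint in the cell), ``comx/comy`` (sums of unwrapped
    Cartesian site coordinates).  ``ux/uy`` store each owned site's
    unwrapped coordinate, assigned from a neighboring site of the same cell
    at conquest time so centers of mass evolve continuously.
    """

    def __init__(self, lattice: HexLattice, max_cells: int = 64):
        self.lattice = lattice
        self.max_cells = int(max_cells)
        self.owner = np.zeros(lattice.n_sites, dtype=np.int64)
        self.ux = np.zeros(lattice.n_sites)
        self.uy = np.zeros(lattice.n_sites)
        n = self.max_cells + 1
        self.area = np.zeros(n, dtype=np.int64)
        self.perim = np.zeros(n, dtype=np.int64)
        self.comx = np.zeros(n)
        self.comy = np.zeros(n)
        self.alive = np.zeros(n, dtype=bool)

    # -- bookkeeping -------------------------------------------------------

    def _grow_cell_arrays(self, need: int) -> None:
        n = len(self.area)
        if need < n:
            return
        new = max(need + 1, 2 * n)
        for name in ("area", "perim"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.zeros(new - n, dtype=arr.dtype)]))
        for name in ("comx", "comy"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.zeros(new - n)]))
        self.alive = np.concatenate([self.alive, np.zeros(new - n, dtype=bool)])
        self.max_cells = new - 1

    def new_cell_id(self) -> int:
        used = np.flatnonzero(self.alive)
        cid = int(used.max()) + 1 if used.size else 1
        self._grow_cell_arrays(cid)
        return cid

    def cell_ids(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def sites_of(self, cell_id: int) -> np.ndarray:
        return np.flatnonzero(self.owner == cell_id)

    # -- mutation ----------------------------------------------------------

    def add_cell(self, sites, cell_id: int | None = None) -> int:
        """Create a cell from a connected site set (BFS-ordered internally)."""
        sites = list(map(int, sites))
        if not sites:
            raise ValueError("cannot create an empty cell")
        if any(self.owner[s] != EMPTY for s in sites):
            raise ValueError("placement overlaps an occupied or forbidden site")
        cid = self.new_cell_id() if cell_id is None else int(cell_id)
        self._grow_cell_arrays(cid)
        if self.alive[cid]:
            raise ValueError(f"cell id {cid} already in use")
        self.alive[cid] = True
        site_set = set(sites)
        # BFS from the first site so unwrapped coordinates chain consistently
        order = [sites[0]]
        seen = {sites[0]}
        qi = 0
        while qi < len(order):
            cur = order[qi]
            qi += 1
            for n in self.lattice.neigh[cur]:
                if n >= 0 and n in site_set and n not in seen:
                    seen.add(int(n))
                    order.append(int(n))
        if len(order) != len(site_set):
            raise ValueError("cell site set is not connected")
        self.ux[order[0]] = self.lattice.cx[order[0]]
        self.uy[order[0]] = self.lattice.cy[order[0]]
        self.owner[order[0]] = cid
        self.area[cid] = 1
        self.perim[cid] = int(sum(1 for n in self.lattice.neigh[order[0]] if n >= 0))
        self.comx[cid] = self.ux[order[0]]
        self.comy[cid] = self.uy[order[0]]
        for s in order[1:]:
            src = next(n for n in self.lattice.neigh[s] if n >= 0 and self.owner[n] == cid)
            self.add_site(cid, s, int(src))
        return cid

    def add_site(self, cell_id: int, site: int, source_site: int | None = None) -> None:
        """Cell ``cell_id`` conquers ``site`` (must currently be EMPTY)."""
        if self.owner[site] != EMPTY:
            raise ValueError("target site is not empty")
        lat = self.lattice
        dP = 0
        for n in lat.neigh[site]:
            if n < 0:
                continue
            dP += -1 if self.owner[n] == cell_id else 1
        if source_site is not None:
            dx, dy = lat.wrap_delta(lat.cx[site] - lat.cx[source_site],
                                    lat.cy[site] - lat.cy[source_site])
            self.ux[site] = self.ux[source_site] + dx
            self.uy[site] = self.uy[source_site] + dy
        else:
            self.ux[site] = lat.cx[site]
            self.uy[site] = lat.cy[site]
        self.owner[site] = cell_id
        self.area[cell_id] += 1
        self.perim[cell_id] += dP
        self.comx[cell_id] += self.ux[site]
        self.comy[cell_id] += self.uy[site]

    def remove_site(self, cell_id: int, site: int) -> None:
        """Cell ``cell_id`` loses ``site`` (becomes EMPTY)."""
        if self.owner[site] != cell_id:
            raise ValueError("site not owned by cell")
        lat = self.lattice
        dP = 0
        for n in lat.neigh[site]:
            if n < 0:
                continue
            dP += 1 if self.owner[n] == cell_id else -1
        self.owner[site] = EMPTY
        self.area[cell_id] -= 1
        self.perim[cell_id] += dP
        self.comx[cell_id] -= self.ux[site]
        self.comy[cell_id] -= self.uy[site]
        if self.area[cell_id] == 0:
            self.alive[cell_id] = False
            self.perim[cell_id] = 0

    # -- queries -----------------------------------------------------------

    def center_of_mass(self, cell_id: int) -> tuple[float, float]:
        """Mean unwrapped Cartesian coordinate of the cell's sites."""
        if not self.alive[cell_id] or self.area[cell_id] == 0:
            raise ValueError(f"cell {cell_id} is empty")
        a = self.area[cell_id]
        return float(self.comx[cell_id] / a), float(self.comy[cell_id] / a)

    def recount(self, cell_id: int) -> tuple[int, int]:
        """Area and perimeter recomputed from scratch (cache oracle)."""
        sites = self.sites_of(cell_id)
        area = len(sites)
        perim = 0
        for s in sites:
            for n in self.lattice.neigh[s]:
                if n >= 0 and self.owner[n] != cell_id:
                    perim += 1
        return area, perim

    def check_caches(self) -> None:
        """Assert every cached area/perimeter equals a scratch recount."""
        for cid in self.cell_ids():
            area, perim = self.recount(cid)
            if area != self.area[cid] or perim != self.perim[cid]:
                raise AssertionError(
                    f"cache drift for cell {cid}: cached (A={self.area[cid]}, "
                    f"P={self.perim[cid]}) vs recount (A={area}, P={perim})")

    def site_accounting_ok(self) -> bool:
        """Sum of cell areas + empty + forbidden sites == total sites."""
        n_cells = int(self.area[self.alive].sum())
        n_empty = int(np.sum(self.owner == EMPTY))
        n_wall = int(np.sum(self.owner == WALL))
        return n_cells + n_empty + n_wall == self.lattice.n_sites


def compact_blob(lattice: HexLattice, center_site: int, area: int,
                 allowed: np.ndarray | None = None) -> list[int]:
    """A compact, connected site set of given area grown by BFS from a center.

    ``allowed`` is an optional boolean mask of admissible sites (e.g. a
    micropattern); growth never leaves it.
    """
    if area < 1:
        raise ValueError("blob area must be >= 1")
    if allowed is not None and not allowed[center_site]:
        raise ValueError("center site not admissible")
    seen = {int(center_site)}
    order = [int(center_site)]
    qi = 0
    while len(order) < area and qi < len(order):
        cur = order[qi]
        qi += 1
        for n in lattice.neigh[cur]:
            if n >= 0 and n not in seen and (allowed is None or allowed[n]):
                seen.add(int(n))
                order.append(int(n))
                if len(order) == area:
                    break
    if len(order) < area:
        raise ValueError("not enough admissible sites to place blob")
    return order
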