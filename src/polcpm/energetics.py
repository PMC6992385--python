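"""Effective energy of cell configurations and elementary-event energy differences.

The energy of one cell combines contractile elasticity of membrane and
cortex with the cytoskeletal polarization field:

    H_cont = kappa_A * A^2 + kappa_P * P^2          (area A, perimeter P)
    H_cyto = - sum_x eps(x)                          (over occupied sites)

A is the substrate contact area in site counts; P is the physical contour
length of the contact area: each boundary edge of the hexagonal tiling is
one hexagon side, of length 1/sqrt(3) at unit lattice constant, so
P = (boundary-edge count) / sqrt(3).  With the published stiffnesses
(kappa_P ~ 0.06-0.12 at kBT = 1) this contour-length convention is what
makes elementary protrusions at a polarized front thermally accessible;
see :func:`perimeter_length`.

Cell-cell contacts contribute an adhesion benefit ``-B`` per contact edge;
rupturing an existing contact costs ``B + delta_B`` (the extra ``delta_B``
is dissipative friction, not part of the Hamiltonian).  Losing a site also
ruptures that site's substrate bonds at dissipative cost ``D``.  Elementary
events (a source site conquering a neighboring target site) are accepted
with Metropolis probability at thermal scale ``kBT``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .hexgrid import EDGE_LENGTH, EMPTY, WALL, ConfigurationError

__all__ = [
    "ModelParams",
    "EventKind",
    "EventProposal",
    "contractile_energy",
    "cytoskeletal_energy",
    "acceptance_probability",
    "adhesion_delta",
    "compact_cluster_perimeter",
    "equilibrium_area",
]


@dataclass
class ModelParams:
    """Hamiltonian, feedback, adhesion, and thermal parameters of one cell type.

    Units: energies in units of kBT (kBT = 1 by convention); areas in sites;
    perimeters in boundary-edge counts; rates per MCS.

    Attributes
    ----------
    kappa_A, kappa_P
        Area and perimeter stiffness (contractility).
    eps0
        Resting value of the polarization field (energy gain per occupied
        site); together with ``kappa_A`` it sets the cell size, A* ~ eps0/(2 kappa_A).
    delta_eps
        Maximum cell polarity: eps stays within [eps0 - delta_eps/2, eps0 + delta_eps/2].
        The ratio delta_eps/kappa_P ("specific polarizability") is the
        relevant control parameter for motility.
    R
        Signaling radius (hex graph distance) of the protrusion/retraction
        feedback on the polarization field.
    mu
        Cytoskeletal update rate per MCS (0 < mu <= 1); 1/mu is the
        intrinsic relaxation timescale of the polarization field.
    B, delta_B
        Cell-cell adhesion benefit per contact edge and the extra
        dissipative cost of rupturing an existing contact.
    D
        Cell-substrate dissipation per lost site.
    kBT
        Thermal energy scale of the Metropolis kinetics.
    phi_mode
        How a substrate field phi modifies the polarization energy of a
        site: 'additive' (eps -> eps + phi) or 'multiplicative' (eps -> eps * phi).
    friction_mode
        When the dissipative rupture cost delta_B is charged for a
        destroyed cell-cell contact edge: 'separation' (default — only
        when the contact truly separates, i.e. the site becomes empty;
        junction migration during displacement pays only the reversible
        +-B) or 'per_edge' (every destroyed contact edge, which at
        delta_B of order 10 kBT freezes confluent interfaces entirely).
    """

    kappa_A: float
    kappa_P: float
    eps0: float
    delta_eps: float
    R: int = 5
    mu: float = 0.1
    B: float = 0.0
    delta_B: float = 0.0
    D: float = 0.0
    kBT: float = 1.0
    phi_mode: str = "additive"
    friction_mode: str = "separation"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.kappa_A < 0 or self.kappa_P < 0:
            raise ConfigurationError("stiffnesses kappa_A, kappa_P must be >= 0")
        if self.delta_eps < 0:
            raise ConfigurationError("delta_eps must be >= 0")
        if not self.eps0 > self.delta_eps / 2:
            raise ConfigurationError("eps0 must exceed delta_eps/2 (lower eps bound positive)")
        if not (0 < self.mu <= 1):
            raise ConfigurationError("update rate mu must satisfy 0 < mu <= 1")
        if self.delta_B < 0 or self.D < 0:
            raise ConfigurationError("delta_B and D must be >= 0")
        if self.kBT <= 0:
            raise ConfigurationError("kBT must be > 0")
        if int(self.R) != self.R or self.R < 0:
            raise ConfigurationError("signaling radius R must be a non-negative integer")
        if self.phi_mode not in ("additive", "multiplicative"):
            raise ConfigurationError("phi_mode must be 'additive' or 'multiplicative'")
        if self.friction_mode not in ("separation", "per_edge"):
            raise ConfigurationError("friction_mode must be 'separation' or 'per_edge'")

    @property
    def eps_min(self) -> float:
        return self.eps0 - self.delta_eps / 2

    @property
    def eps_max(self) -> float:
        return self.eps0 + self.delta_eps / 2

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


class EventKind(Enum):
    PROTRUSION_INTO_EMPTY = "protrusion_into_empty"
    PROTRUSION_INTO_CELL = "protrusion_into_cell"
    RETRACTION = "retraction"


@dataclass(frozen=True)
class EventProposal:
    """A directed elementary event: the source site's owner conquers the target site."""
    kind: EventKind
    source_site: int
    target_site: int
    source_cell: int
    target_cell: int

    @staticmethod
    def classify(source_cell: int, target_cell: int,
                 source_site: int, target_site: int) -> "EventProposal":
        if source_cell == target_cell:
            raise ValueError("proposal between sites of the same owner")
        if source_cell == WALL or target_cell == WALL:
            raise ValueError("proposal involving a forbidden wall site")
        if source_cell == EMPTY:
            kind = EventKind.RETRACTION
        elif target_cell == EMPTY:
            kind = EventKind.PROTRUSION_INTO_EMPTY
        else:
            kind = EventKind.PROTRUSION_INTO_CELL
        return EventProposal(kind, source_site, target_site, source_cell, target_cell)


# ---------------------------------------------------------------------------
# Energy terms
# ---------------------------------------------------------------------------

def perimeter_length(edge_count: float) -> float:
    """Contour length of a cell boundary from its lattice-edge count."""
    return float(edge_count) * EDGE_LENGTH


def contractile_energy(A: float, P: float, params: ModelParams) -> float:
    """Elastic energy kappa_A * A^2 + kappa_P * P^2 of one cell.

    ``P`` is the contour length (use :func:`perimeter_length` to convert a
    boundary-edge count).
    """
    if A < 0 or P < 0:
        raise ValueError("area and perimeter must be >= 0")
    return params.kappa_A * A * A + params.kappa_P * P * P


def cytoskeletal_energy(polarization_values) -> float:
    """Negative sum of the polarization field over a cell's occupied sites."""
    vals = np.asarray(polarization_values, dtype=float)
    if vals.size == 0:
        return 0.0
    return -float(vals.sum())


def acceptance_probability(delta_H: float, kBT: float = 1.0) -> float:
    """Metropolis rule min(1, exp(-delta_H / kBT))."""
    if kBT <= 0:
        raise ValueError("kBT must be > 0")
    x = -delta_H / kBT
    if x >= 0:
        return 1.0
    return float(np.exp(x))


def adhesion_delta(config, proposal: EventProposal, params: ModelParams) -> float:
    """Adhesion/friction energy difference of an elementary event.

    Counted on the 6-neighborhood of the target site: every existing
    cell-cell contact edge of the target is destroyed (+B each, as the
    surface-energy term -B per contact edge loses it), and each neighbor
    belonging to another cell forms a new contact with the conqueror
    (benefit -B each).  The dissipative rupture surcharge delta_B applies
    per destroyed edge according to ``params.friction_mode``: always
    ('per_edge'), or only when the contact truly separates, i.e. on
    retraction into empty medium ('separation', default).
    """
    b = proposal.target_site
    l = proposal.target_cell
    g = proposal.source_cell
    created = destroyed = 0
    for n in config.lattice.neigh[b]:
        if n < 0:
            continue
        w = config.owner[n]
        if l > 0 and w > 0 and w != l:
            destroyed += 1
        if g > 0 and w > 0 and w != g:
            created += 1
    dH = -params.B * created + params.B * destroyed
    if destroyed and (params.friction_mode == "per_edge" or g == EMPTY):
        dH += params.delta_B * destroyed
    return dH


# ---------------------------------------------------------------------------
# Independent steady-state oracle: 1-D minimization over compact shapes
# ---------------------------------------------------------------------------

def compact_cluster_perimeter(max_area: int) -> np.ndarray:
    """Boundary-edge counts P(A) of near-minimal-perimeter hex clusters.

    Grows a cluster greedily on an unbounded lattice, always adding the
    frontier site with the most occupied neighbors, and records the
    perimeter after each addition.  Entry ``out[A]`` is P for A sites
    (``out[0] = 0``).
    """
    # axial-coordinate neighbors on an unbounded lattice
    dirs = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]
    occupied = set()
    frontier: dict[tuple[int, int], int] = {(0, 0): 0}
    out = np.zeros(max_area + 1, dtype=np.int64)
    P = 0
    for A in range(1, max_area + 1):
        # most occupied neighbors; deterministic tie-break by coordinates
        best = max(frontier.items(), key=lambda kv: (kv[1], -abs(kv[0][0]) - abs(kv[0][1]),
                                                     kv[0]))[0]
        nocc = frontier.pop(best)
        occupied.add(best)
        P += 6 - 2 * nocc
        for d in dirs:
            nb = (best[0] + d[0], best[1] + d[1])
            if nb in occupied:
                continue
            frontier[nb] = frontier.get(nb, 0) + 1
        out[A] = P
    return out


def equilibrium_area(params: ModelParams, max_area: int | None = None) -> int:
    """Steady-state area of a solitary unpolarized cell.

    Minimizes kappa_A A^2 + kappa_P P(A)^2 - eps0 A over compact lattice
    shapes, with P(A) from :func:`compact_cluster_perimeter`.  Serves as an
    independent oracle for the Monte Carlo steady state.
    """
    if max_area is None:
        max_area = max(16, int(np.ceil(params.eps0 / max(params.kappa_A, 1e-12))) + 8)
    P = compact_cluster_perimeter(max_area) * EDGE_LENGTH
    A = np.arange(max_area + 1)
    H = params.kappa_A * A.astype(float) ** 2 + params.kappa_P * P ** 2 \
        - params.eps0 * A
    return int(np.argmin(H[1:]) + 1)
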