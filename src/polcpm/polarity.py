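"""Self-regulating polarization field and its once-per-MCS feedback update.

Each occupied site x carries a polarization value eps(x) in
[eps0 - delta_eps/2, eps0 + delta_eps/2], subsuming local cytoskeletal
mass and cell-substrate adhesion strength.  During one MCS every accepted
protrusion (retraction) increments (decrements) an integer regulatory
accumulator F at all sites of the participating cells within hex distance
R of the event.  At the end of the MCS the field relaxes with rate mu
toward a target selected by the *sign* of F — the upper bound for F > 0,
the lower bound for F < 0, the rest value eps0 for F = 0 — after which the
accumulators are reset.  Newly conquered sites inherit the conqueror's eps
and start with F = 0.

These are the reference (pure numpy) implementations; the Monte Carlo
kernel applies the identical rules incrementally.
"""

from __future__ import annotations

import numpy as np

from .energetics import ModelParams

__all__ = [
    "record_feedback",
    "apply_polarization_update",
    "polarization_bounds_ok",
]


def record_feedback(F: np.ndarray, owner: np.ndarray, lattice, event_site: int,
                    gaining_cell: int, losing_cell: int, R: int) -> None:
    """Apply the integer feedback of one ACCEPTED event at ``event_site``.

    +1 on sites of ``gaining_cell`` and -1 on sites of ``losing_cell``
    within hex distance R (either cell id may be 0 = absent).  Must only be
    called for accepted events, with the post-event owner map.
    """
    disk = lattice.disk_neighborhood(event_site, R)
    w = owner[disk]
    if gaining_cell > 0:
        F[disk[w == gaining_cell]] += 1
    if losing_cell > 0:
        F[disk[w == losing_cell]] -= 1


def apply_polarization_update(eps: np.ndarray, F: np.ndarray, owner: np.ndarray,
                              params: ModelParams,
                              deps_eff: float | np.ndarray | None = None) -> None:
    """End-of-MCS relaxation of eps toward the F-sign-selected target; resets F.

    With rate mu: F>0 pulls eps toward eps0 + deps/2, F<0 toward
    eps0 - deps/2, F=0 toward the rest value eps0.  ``deps_eff`` overrides
    the polarizability (e.g. 0 during mitotic rounding).  The bounds
    invariant is preserved automatically because the targets are the bounds
    themselves and 0 < mu <= 1.
    """
    if deps_eff is None:
        deps_eff = params.delta_eps
    occ = owner > 0
    half = 0.5 * np.broadcast_to(np.asarray(deps_eff, float), eps.shape)
    target = np.full(eps.shape, float(params.eps0))
    target[F > 0] = params.eps0 + half[F > 0]
    target[F < 0] = params.eps0 - half[F < 0]
    eps[occ] += params.mu * (target[occ] - eps[occ])
    F[:] = 0


def polarization_bounds_ok(eps: np.ndarray, owner: np.ndarray,
                           params: ModelParams, atol: float = 1e-9) -> bool:
    """Check eps in [eps0 - deps/2, eps0 + deps/2] on occupied sites, 0 elsewhere."""
    occ = owner > 0
    if np.any(eps[~occ] != 0):
        return False
    vals = eps[occ]
    return bool(np.all(vals >= params.eps_min - atol)
                and np.all(vals <= params.eps_max + atol))
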