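"""Micropatterned substrates: adhesive fields phi and impenetrable walls.

A substrate field assigns every lattice site either an energy offset phi
(modulating the polarization energy a cell gains there) or the FORBIDDEN
flag.  Forbidden sites act as impenetrable walls: cells can never occupy
them, matching the limit phi -> -infinity.  Finite phi is retained for
soft patterns, applied either additively (eps -> eps + phi) or
multiplicatively (eps -> eps * phi).
"""

from __future__ import annotations

import numpy as np

from .hexgrid import HexLattice, ConfigurationError

__all__ = [
    "SubstrateField",
    "circular_pattern",
    "strip_walls",
    "apply_phi_penalty",
    "phi_from_table",
]

FORBIDDEN = "forbidden"


class SubstrateField:
    """Per-site adhesion offsets plus a forbidden-site mask."""

    def __init__(self, lattice: HexLattice, phi: np.ndarray | None = None,
                 forbidden: np.ndarray | None = None):
        self.lattice = lattice
        self.phi = np.zeros(lattice.n_sites) if phi is None else np.asarray(phi, float)
        self.forbidden = (np.zeros(lattice.n_sites, dtype=bool)
                          if forbidden is None else np.asarray(forbidden, bool))
        if self.phi.shape != (lattice.n_sites,) or self.forbidden.shape != (lattice.n_sites,):
            raise ConfigurationError("substrate field shape does not match lattice")
        if np.any(self.phi > 0):
            raise ConfigurationError("phi offsets must be <= 0")

    @property
    def admissible(self) -> np.ndarray:
        return ~self.forbidden


def circular_pattern(lattice: HexLattice, center: tuple[float, float] | None,
                     r0: float) -> SubstrateField:
    """Adhesive island: phi = 0 within Cartesian distance r0 of center, walls outside."""
    if r0 <= 0:
        raise ConfigurationError("confinement radius r0 must be > 0")
    if center is None:
        center = (lattice.width / 2.0, lattice.height / 2.0)
    if 2 * r0 > min(lattice.width, lattice.height):
        raise ConfigurationError("confinement radius exceeds half the lattice extent")
    dx = lattice.cx - center[0]
    dy = lattice.cy - center[1]
    if lattice.boundary_x == "periodic":
        dx = dx - lattice.width * np.round(dx / lattice.width)
    if lattice.boundary_y == "periodic":
        dy = dy - lattice.height * np.round(dy / lattice.height)
    outside = dx * dx + dy * dy >= r0 * r0
    return SubstrateField(lattice, forbidden=outside)


def strip_walls(lattice: HexLattice, x_left: float, x_right: float) -> SubstrateField:
    """Impenetrable walls outside the band x_left <= x <= x_right (periodic in y)."""
    if not x_left < x_right:
        raise ConfigurationError("x_left must be < x_right")
    outside = (lattice.cx < x_left) | (lattice.cx > x_right)
    return SubstrateField(lattice, forbidden=outside)


def phi_from_table(lattice: HexLattice, path) -> SubstrateField:
    """Arbitrary phi raster from a delimited-text table.

    Whitespace/tab-delimited columns ``q  r  phi`` (with an optional
    header line); sites not listed keep phi = 0, and non-finite phi
    entries (e.g. ``-inf``) mark the site forbidden.
    """
    import pandas as pd
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if not {"q", "r", "phi"} <= set(cols):
        raise ConfigurationError(f"{path}: need columns q, r, phi")
    phi = np.zeros(lattice.n_sites)
    forbidden = np.zeros(lattice.n_sites, dtype=bool)
    for q, r, val in df[[cols["q"], cols["r"], cols["phi"]]].itertuples(index=False):
        site = lattice.site_index(int(q), int(r))
        if np.isfinite(val):
            phi[site] = float(val)
        else:
            forbidden[site] = True
    return SubstrateField(lattice, phi=phi, forbidden=forbidden)


def apply_phi_penalty(phi_value: float, eps_value: float, mode: str) -> float | None:
    """Effective polarization energy a protruding cell gains on a penalized site.

    Returns None for mode 'forbidden' (the move is rejected outright).
    """
    if mode == "additive":
        return eps_value + phi_value
    if mode == "multiplicative":
        return eps_value * phi_value
    if mode == FORBIDDEN:
        return None
    raise ConfigurationError(f"unknown phi mode {mode!r}")
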