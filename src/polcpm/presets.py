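"""Bundled parameter presets for the published experiment setups.

Each preset is a nested dict in the same schema the config loader accepts,
reproducing one figure's parameter list verbatim: the single-cell
persistent-migration setup, the signaling-radius sweep, the 4-cell
micropattern rotation setup, and the four expanding-monolayer regimes
(migration-dominated, proliferation-dominated, and the two fingering
variants).  Sweep quantities without a caption value (e.g. the maximum
cell polarity in the single-cell sweep) carry a representative default.
"""

from __future__ import annotations

import copy

__all__ = ["PRESETS", "figure_preset"]

PRESETS: dict[str, dict] = {
    # single cell, persistent random walk statistics
    "fig2": {
        "experiment": "single",
        "model": {
            "kappa_A": 0.18, "kappa_P": 0.060, "eps0": 225.0, "delta_eps": 36.0,
            "R": 5, "mu": 0.1, "B": 0.0, "delta_B": 0.0, "D": 0.0, "kBT": 1.0,
        },
        "environment": {"pattern": "none"},
        "run": {"T_sim": 10000, "replicates": 100, "n_cols": 300, "n_rows": 300,
                "record_every": 1},
    },
    # single cell, signaling-radius sweep
    "fig3": {
        "experiment": "single",
        "model": {
            "kappa_A": 0.18, "kappa_P": 0.060, "eps0": 225.0, "delta_eps": 36.0,
            "R": 5, "mu": 0.1, "B": 0.0, "delta_B": 0.0, "D": 0.0, "kBT": 1.0,
        },
        "environment": {"pattern": "none"},
        "run": {"T_sim": 10000, "replicates": 100, "n_cols": 300, "n_rows": 300,
                "record_every": 1},
    },
    # 4-cell cluster on a circular micropattern
    "fig4": {
        "experiment": "rotation",
        "model": {
            "kappa_A": 0.18, "kappa_P": 0.060, "eps0": 225.0, "delta_eps": 30.0,
            "R": 5, "mu": 0.1, "B": 0.0, "delta_B": 12.0, "D": 0.0, "kBT": 1.0,
        },
        "environment": {"pattern": "circle", "r0": 30.6},
        "run": {"T_sim": 10000, "replicates": 100, "n_cells": 4,
                "n_cols": 96, "n_rows": 112, "record_every": 1},
    },
    # expanding monolayer, migration-dominated (no division)
    "fig5ad": {
        "experiment": "tissue",
        "model": {
            "kappa_A": 0.18, "kappa_P": 0.12, "eps0": 35.0, "delta_eps": 30.0,
            "R": 2, "mu": 0.1, "B": 12.0, "delta_B": 0.0, "D": 0.0, "kBT": 1.0,
        },
        "cycle": {"enabled": False},
        "environment": {"pattern": "strip", "x_left": -175.0, "x_right": 175.0},
        "run": {"T_sim": 3000, "replicates": 100, "n_cells": 3300, "record_every": 10},
    },
    # expanding monolayer, proliferation-dominated
    "fig5eh": {
        "experiment": "tissue",
        "model": {
            "kappa_A": 0.18, "kappa_P": 0.12, "eps0": 35.0, "delta_eps": 10.0,
            "R": 2, "mu": 0.1, "B": 12.0, "delta_B": 0.0, "D": 0.0, "kBT": 1.0,
        },
        "cycle": {"enabled": True, "Tg": 180, "Td": 20, "A_T": 1.0},
        "environment": {"pattern": "strip", "x_left": -175.0, "x_right": 175.0},
        "run": {"T_sim": 3000, "replicates": 100, "n_cells": 2500, "record_every": 10},
    },
    # fingering fronts, quickly dividing
    "fig6ad": {
        "experiment": "tissue",
        "model": {
            "kappa_A": 0.18, "kappa_P": 0.10, "eps0": 35.0, "delta_eps": 20.0,
            "R": 5, "mu": 0.1, "B": 5.0, "delta_B": 10.0, "D": 0.0, "kBT": 1.0,
        },
        "cycle": {"enabled": True, "Tg": 180, "Td": 20, "A_T": 1.05},
        "environment": {"pattern": "strip", "x_left": -175.0, "x_right": 175.0},
        "run": {"T_sim": 3000, "replicates": 100, "n_cells": 2500, "record_every": 10},
    },
    # fingering fronts, slowly dividing
    "fig6eh": {
        "experiment": "tissue",
        "model": {
            "kappa_A": 0.18, "kappa_P": 0.10, "eps0": 35.0, "delta_eps": 20.0,
            "R": 5, "mu": 0.1, "B": 5.0, "delta_B": 10.0, "D": 0.0, "kBT": 1.0,
        },
        "cycle": {"enabled": True, "Tg": 180, "Td": 20, "A_T": 1.10},
        "environment": {"pattern": "strip", "x_left": -175.0, "x_right": 175.0},
        "run": {"T_sim": 3000, "replicates": 100, "n_cells": 2500, "record_every": 10},
    },
}


def figure_preset(name: str) -> dict:
    """Deep copy of a bundled preset (raises KeyError with options listed)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return copy.deepcopy(PRESETS[name])
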