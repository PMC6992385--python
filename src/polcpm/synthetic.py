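"""Synthetic trajectory generators used as closed-form oracles for the analysis layer.

The persistent-random-walk generator moves walkers at constant speed while
their heading angle diffuses with angular diffusion constant 1/tau_p, so
the orientation decorrelates as exp(-tau/tau_p) and the MSD follows the
2-D Fuerth form exactly in the ensemble limit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "generate_prw",
    "generate_ballistic",
    "generate_circle",
    "generate_random_walk",
]


def generate_prw(v: float, tau_p: float, n_steps: int, n_walkers: int = 1,
                 dt: float = 1.0, seed: int = 0) -> np.ndarray:
    """Persistent random walks: (n_walkers, n_steps + 1, 2) positions.

    ``tau_p = inf`` yields straight lines; small ``tau_p`` approaches pure
    diffusion with D = v^2 tau_p / 2.
    """
    if v <= 0 or not tau_p > 0:
        raise ValueError("v and tau_p must be > 0")
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0, 2 * np.pi, size=n_walkers)
    if np.isinf(tau_p):
        dtheta = np.zeros((n_walkers, n_steps))
    else:
        dtheta = rng.normal(0.0, np.sqrt(2.0 * dt / tau_p), size=(n_walkers, n_steps))
    theta = theta0[:, None] + np.concatenate(
        [np.zeros((n_walkers, 1)), np.cumsum(dtheta, axis=1)], axis=1)
    steps = v * dt * np.stack([np.cos(theta[:, :-1]), np.sin(theta[:, :-1])], axis=-1)
    pos = np.concatenate([np.zeros((n_walkers, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    return pos


def generate_ballistic(v: float, heading: float, n_steps: int,
                       dt: float = 1.0) -> np.ndarray:
    """Uniform straight-line motion: (n_steps + 1, 2) positions."""
    t = np.arange(n_steps + 1) * dt
    return np.stack([v * t * np.cos(heading), v * t * np.sin(heading)], axis=-1)


def generate_circle(radius: float, omega: float, n_steps: int, dt: float = 1.0,
                    noise: float = 0.0, seed: int = 0) -> np.ndarray:
    """Circular motion of given radius and signed angular velocity, plus noise."""
    t = np.arange(n_steps + 1) * dt
    pos = radius * np.stack([np.cos(omega * t), np.sin(omega * t)], axis=-1)
    if noise > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.normal(0.0, noise, size=pos.shape)
    return pos


def generate_random_walk(step: float, n_steps: int, n_walkers: int = 1,
                         seed: int = 0) -> np.ndarray:
    """Isotropic Gaussian random walks (pure diffusion reference)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step, size=(n_walkers, n_steps, 2))
    return np.concatenate([np.zeros((n_walkers, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
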