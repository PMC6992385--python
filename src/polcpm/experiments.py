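"""Experiment harnesses: free single cell, confined cluster, expanding monolayer.

These functions wire lattice, environment, placement, recorders and
analysis together for the three published setups, at configurable problem
size.  Single-cell and cluster harnesses default to the published
reference parameters (the boundary-local attempt budget makes them cheap
even at full cell size); the monolayer harness is the genuinely scaled
part — narrower strips with proportionally fewer cells, prepared directly
in the confluent state.
"""

from __future__ import annotations

import numpy as np

from .energetics import ModelParams, equilibrium_area
from .engine import (Simulation, TissueRecorder, TrajectoryRecorder,
                     place_cluster_on_disk, place_confluent_strip, place_single_cell)
from .environment import circular_pattern, strip_walls
from .hexgrid import SQRT3_2, build_lattice
from .observables import (cluster_angular_velocity, correlation_time,
                          dominant_period, fit_prw, msd, msd_loglog_slope,
                          vacf, velocities)
from .proliferation import CycleParams, calibrate_reference_area

__all__ = [
    "single_cell_params",
    "run_single_cell",
    "single_cell_ensemble",
    "analyze_prw_ensemble",
    "motility_sweep",
    "classify_motile",
    "onset_bracket",
    "quarter_rise_onset",
    "run_rotation",
    "rotation_sweep",
    "scaled_rotation_radius",
    "make_tissue_sim",
    "run_tissue",
    "burst_period",
]


# ---------------------------------------------------------------------------
# Single cell
# ---------------------------------------------------------------------------

def single_cell_params(ratio: float, eps0: float = 225.0, kappa_P: float = 0.060,
                       kappa_A: float = 0.18, R: int = 5, mu: float = 0.1,
                       **kw) -> ModelParams:
    """Reference single-cell parameters at a given specific polarizability.

    ``ratio`` is delta_eps / kappa_P; eps0 = 225 is the published reference
    (it sets the cell size ~ eps0 / (2 kappa_A) and, with it, the contour
    length that the motility threshold tracks — lower it only for
    qualitative toy runs).
    """
    return ModelParams(kappa_A=kappa_A, kappa_P=kappa_P, eps0=eps0,
                       delta_eps=ratio * kappa_P, R=R, mu=mu, **kw)


def _lattice_side_for(params: ModelParams) -> int:
    side = int(np.ceil(6.0 * np.sqrt(equilibrium_area(params)))) + 8
    return side + side % 2


def run_single_cell(params: ModelParams, T: int, seed: int,
                    lattice_side: int | None = None,
                    record_every: int = 1) -> dict:
    """One free cell on a periodic lattice; returns its recorded time series."""
    side = lattice_side or _lattice_side_for(params)
    lat = build_lattice(side, side)
    sim = Simulation(lat, params, seed=seed, max_cells=4)
    cid = place_single_cell(sim, area=equilibrium_area(params))
    rec = TrajectoryRecorder(interval=record_every)
    sim.run(T, recorders=[rec])
    arr = rec.arrays()
    return {
        "t": arr["t"],
        "com": arr["com"][:, cid, :],
        "area": arr["area"][:, cid],
        "perim": arr["perim"][:, cid],
        "sim": sim,
        "cell_id": cid,
    }


def single_cell_ensemble(params: ModelParams, T: int, n_rep: int, seed: int,
                         lattice_side: int | None = None,
                         record_every: int = 1) -> np.ndarray:
    """Replicate runs with spawned seeds; stacked COM array (n_rep, T_rec, 2)."""
    seeds = np.random.SeedSequence(seed).generate_state(n_rep) % (2 ** 31)
    out = []
    for s in seeds:
        out.append(run_single_cell(params, T, int(s), lattice_side,
                                   record_every)["com"])
    return np.stack(out)


def analyze_prw_ensemble(com: np.ndarray, record_dt: float = 1.0,
                         window: int = 10, discard: int = 200) -> dict:
    """PRW statistics of an ensemble of COM trajectories.

    Discards the initial polarization transient, computes the
    time-and-ensemble MSD on a log-spaced lag grid, fits the Fuerth form,
    and reports speed, persistence time, and the short-lag log-log slope.
    """
    n_discard = min(int(discard / record_dt), com.shape[1] // 2)
    com = com[:, n_discard:, :]
    T = com.shape[1]
    lags = np.unique(np.geomspace(1, max(2, T // 3), 40).astype(int))
    m = msd(com, lags)
    fit = fit_prw(lags * record_dt, m)
    slope_short = slope_long = tau_vacf = np.nan
    if fit.converged and np.isfinite(fit.tau_p):
        short = lags * record_dt < max(fit.tau_p / 3.0, 3 * record_dt)
        if short.sum() >= 2:
            slope_short = msd_loglog_slope(lags * record_dt, m, short)
        long = lags * record_dt > 3.0 * fit.tau_p
        if long.sum() >= 3:
            slope_long = msd_loglog_slope(lags * record_dt, m, long)
        # heading-autocorrelation time (integral estimator)
        w = max(1, int(window / record_dt))
        vel = velocities(com, window=w, dt=record_dt)
        lmax = int(min(4 * fit.tau_p / record_dt, com.shape[1] - w - 2))
        if lmax > 10:
            vl = np.arange(0, lmax, max(1, lmax // 200))
            C = vacf(vel, vl)
            try:
                tau_vacf = correlation_time(vl * record_dt, C,
                                            tail_tau=fit.tau_p)
            except ValueError:
                pass
    # speed from the 10-MCS velocity window as a model-free cross-check
    v_inst = velocities(com, window=max(1, int(window / record_dt)), dt=record_dt)
    speed = float(np.nanmean(np.linalg.norm(v_inst, axis=-1)))
    return {"lags": lags * record_dt, "msd": m, "fit": fit, "speed": speed,
            "slope_short": slope_short, "slope_long": slope_long,
            "tau_vacf": tau_vacf}


def classify_motile(com: np.ndarray, params: ModelParams,
                    record_dt: float = 1.0, displacement_factor: float = 4.0) -> bool:
    """Sustained-migration classifier for one parameter point.

    Motile means the long-lag RMS displacement exceeds
    ``displacement_factor`` cell diameters; immobile cells only show an
    MSD plateau at the cell-size scale.
    """
    a_cart = equilibrium_area(params) * SQRT3_2
    diameter = 2.0 * np.sqrt(a_cart / np.pi)
    T = com.shape[1]
    lag = min(int(1000 / record_dt), (T * 2) // 3)
    m = msd(com, [lag])[0]
    return bool(np.sqrt(m) > displacement_factor * diameter)


def motility_sweep(ratios, T: int = 2000, n_rep: int = 8, seed: int = 1,
                   eps0: float = 225.0, kappa_P: float = 0.060,
                   record_every: int = 1, discard: int = 200) -> list[dict]:
    """Sweep the specific polarizability; returns per-point statistics."""
    rows = []
    for i, ratio in enumerate(ratios):
        params = single_cell_params(ratio, eps0=eps0, kappa_P=kappa_P)
        com = single_cell_ensemble(params, T, n_rep, seed + 1000 * i,
                                   record_every=record_every)
        ana = analyze_prw_ensemble(com, record_dt=record_every, discard=discard)
        rows.append({
            "ratio": float(ratio),
            "motile": classify_motile(com[:, int(discard / record_every):, :],
                                      params, record_dt=record_every),
            "v": ana["fit"].v if ana["fit"].converged else np.nan,
            "tau_p": ana["fit"].tau_p if ana["fit"].converged else np.nan,
            "speed": ana["speed"],
            "slope_short": ana["slope_short"],
            "msd": ana["msd"],
            "lags": ana["lags"],
        })
    return rows


def onset_bracket(grid, flags) -> tuple[float, float]:
    """Bracket [last sub-threshold, first supra-threshold] of a boolean sweep.

    ``flags[i]`` marks grid point i as above threshold; the onset is
    bracketed by the first point from which all flags stay True.
    """
    grid = list(map(float, grid))
    flags = list(map(bool, flags))
    idx = None
    for i in range(len(flags)):
        if all(flags[i:]) and flags[i]:
            idx = i
            break
    if idx is None:
        raise ValueError("no supra-threshold grid points: onset above the grid")
    if idx == 0:
        raise ValueError("all grid points supra-threshold: onset below the grid")
    return grid[idx - 1], grid[idx]


def quarter_rise_onset(grid, values) -> tuple[float, float]:
    """Bracket where a monotone-rising observable passes 25% of its range."""
    v = np.asarray(values, dtype=float)
    thresh = v.min() + 0.25 * (v.max() - v.min())
    return onset_bracket(grid, v > thresh)


# ---------------------------------------------------------------------------
# Confined cluster rotation
# ---------------------------------------------------------------------------

def scaled_rotation_radius(eps0: float, r0_ref: float = 30.6,
                           eps0_ref: float = 225.0) -> float:
    """Confinement radius scaled with the cell's linear size (~ sqrt(eps0))."""
    return r0_ref * np.sqrt(eps0 / eps0_ref)


def run_rotation(params: ModelParams, r0: float, n_cells: int, T: int,
                 seed: int, record_every: int = 1) -> dict:
    """Cell cluster on a circular micropattern; per-cell trajectory series."""
    side = int(np.ceil(2 * r0 + 8))
    n_cols = side + side % 2
    n_rows = int(np.ceil(side / SQRT3_2))
    n_rows += n_rows % 2
    lat = build_lattice(n_cols, n_rows)
    env = circular_pattern(lat, None, r0)
    sim = Simulation(lat, params, environment=env, seed=seed,
                     max_cells=n_cells + 4)
    area = equilibrium_area(params)
    ids = place_cluster_on_disk(sim, n_cells, area, r0)
    rec = TrajectoryRecorder(interval=record_every)
    sim.run(T, recorders=[rec])
    arr = rec.arrays()
    idx = np.asarray(ids, dtype=int)
    return {"t": arr["t"], "com": arr["com"][:, idx, :],
            "perim": arr["perim"][:, idx], "area": arr["area"][:, idx],
            "sim": sim, "ids": ids}


def rotation_omega(com: np.ndarray, record_dt: float = 1.0,
                   window: int = 10, discard: int = 200) -> np.ndarray:
    """Signed cluster angular velocity series from per-cell COM trajectories."""
    com = com[int(discard / record_dt):]
    w = max(1, int(window / record_dt))
    v = velocities(com.transpose(1, 0, 2), window=w, dt=record_dt)  # (C, T-w, 2)
    v = v.transpose(1, 0, 2)
    mid = com[w // 2: w // 2 + v.shape[0]]
    return cluster_angular_velocity(mid, v)


def rotation_sweep(ratios, r0: float, T: int = 3000, n_rep: int = 8,
                   seed: int = 1, eps0: float = 225.0, kappa_P: float = 0.060,
                   n_cells: int = 4, discard: int = 500) -> list[dict]:
    """Sweep the specific polarizability of a confined cluster."""
    rows = []
    for i, ratio in enumerate(ratios):
        params = single_cell_params(ratio, eps0=eps0, kappa_P=kappa_P,
                                    B=0.0, delta_B=12.0)
        omegas = []
        perims = []
        seeds = np.random.SeedSequence(seed + 1000 * i).generate_state(n_rep) % (2 ** 31)
        for s in seeds:
            out = run_rotation(params, r0, n_cells, T, int(s))
            omegas.append(rotation_omega(out["com"], discard=discard))
            perims.append(np.nanmean(out["perim"], axis=1))
        w = np.concatenate(omegas)
        rows.append({
            "ratio": float(ratio),
            "mean_abs_omega": float(np.nanmean(np.abs(w))),
            "std_abs_omega": float(np.nanstd(np.abs(w))),
            "sigma_P": float(np.nanstd(np.concatenate(perims))),
            "omega": omegas,
        })
    return rows


# ---------------------------------------------------------------------------
# Expanding monolayer
# ---------------------------------------------------------------------------

def make_tissue_sim(params: ModelParams, cycle: CycleParams | None,
                    half_width: float, n_cols: int, n_rows: int, seed: int,
                    a_ref: float | None = None,
                    compression: float = 1.05) -> tuple[Simulation, float]:
    """Confluent strip between walls at +-half_width (periodic y).

    The sheet is prepared directly in the pre-grown confluent state (a
    Voronoi tiling of compact cells at ``compression`` times the reference
    density) instead of simulating the slow growth to confluence.
    Returns the simulation and the measured reference area A_ref.
    """
    if a_ref is None:
        a_ref = calibrate_reference_area(params)
    lat = build_lattice(n_cols, n_rows)
    x_mid = lat.width / 2.0
    env = strip_walls(lat, x_mid - half_width, x_mid + half_width)
    n_cells_est = int(2 * half_width * lat.height / (a_ref * SQRT3_2)) + 8
    if cycle is not None and cycle.enabled and cycle.A_ref is None:
        cycle = CycleParams(enabled=True, Tg=cycle.Tg, Td=cycle.Td,
                            A_T=cycle.A_T, A_ref=a_ref,
                            stochastic_rate=cycle.stochastic_rate)
    sim = Simulation(lat, params, environment=env, cycle=cycle, seed=seed,
                     max_cells=max(64, 8 * n_cells_est))
    cell_area = max(4, int(round(a_ref / compression)))
    place_confluent_strip(sim, x_mid - half_width, x_mid + half_width, cell_area)
    return sim, float(a_ref)


def run_tissue(sim: Simulation, T_settle: int, T_record: int,
               record_every: int = 10, n_bins: int = 48) -> TissueRecorder:
    """Settle behind walls, remove them, and record expansion profiles."""
    lat = sim.lattice
    edges = np.linspace(0.0, lat.width, n_bins + 1)
    sim.step(T_settle)
    sim.remove_walls()
    rec = TissueRecorder(interval=record_every, x_edges=edges)
    sim.run(T_record, recorders=[rec])
    return rec


def burst_period(rec: TissueRecorder, record_every: int) -> float:
    """Dominant period (MCS) of the recurrent growth bursts after wall removal.

    Measured from the spacing of division bursts (peaks of the cell-birth
    rate, grouped into contiguous episodes and located by their birth-
    weighted centroids); falls back to the periodogram of the mean-density
    series when fewer than two bursts are resolved.
    """
    births = np.diff(np.asarray(rec.n_cells, dtype=float))
    if births.size >= 4 and births.max() > 0:
        thr = 0.25 * births.max()
        idx = np.flatnonzero(births > thr)
        groups: list[list[int]] = [[int(idx[0])]]
        for i in idx[1:]:
            if i - groups[-1][-1] <= 3:
                groups[-1].append(int(i))
            else:
                groups.append([int(i)])
        centers = []
        for grp in groups:
            g = np.asarray(grp)
            w = births[g]
            centers.append(float(np.sum(g * w) / np.sum(w)))
        if len(centers) >= 2:
            return float(np.mean(np.diff(centers)) * record_every)
    return dominant_period(rec.mean_density(), dt=record_every)
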