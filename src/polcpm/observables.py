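"""Trajectory statistics, shape metrics, rotation metrics, and tissue fields.

Everything here consumes plain numpy arrays produced by the engine's
recorders (or by the synthetic generators), so the estimators can be
validated against closed forms independently of the simulation:

* persistent-random-walk statistics: MSD, velocity autocorrelation, and a
  least-squares fit of the 2-D Fuerth form
  MSD(tau) = 2 v^2 tau_p [tau - tau_p (1 - exp(-tau/tau_p))];
* cell shapes from gyration-tensor eigenvalues;
* trajectory curvature from the smoothed unit tangent;
* signed cluster angular velocity (counter-clockwise positive);
* y-averaged tissue profiles (density, sigma_xx, v_x) and kymographs, with
  per-cell isotropic stress from a virtual uniform dilation of the energy:
  Pi = eps_mean - 2 kappa_A_eff A - kappa_P_eff P^2 / A (tension positive,
  ~0 for a solitary cell at its equilibrium area);
* leading-edge roughness of an expanding front.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "msd",
    "vacf",
    "velocities",
    "orientations",
    "furth_msd",
    "PRWFit",
    "fit_prw",
    "correlation_time",
    "msd_loglog_slope",
    "shape_metrics",
    "trajectory_curvature",
    "cluster_angular_velocity",
    "rotation_stats",
    "cell_pressure",
    "density_profile",
    "stress_profile",
    "velocity_profile",
    "Kymograph",
    "tissue_kymographs",
    "first_crossing_times",
    "front_profile",
    "front_roughness",
    "roughness_of_profile",
    "dominant_period",
]


# ---------------------------------------------------------------------------
# Trajectory statistics
# ---------------------------------------------------------------------------

def _as_ensemble(positions: np.ndarray) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    if pos.ndim != 3 or pos.shape[-1] != 2:
        raise ValueError("positions must be (T, 2) or (n_rep, T, 2)")
    return pos


def msd(positions: np.ndarray, lags) -> np.ndarray:
    """Time-and-ensemble averaged mean squared displacement.

    ``positions`` is (T, 2) or (n_rep, T, 2) of unwrapped coordinates
    sampled at unit intervals of the caller's choosing; ``lags`` are sample
    offsets.
    """
    pos = _as_ensemble(positions)
    lags = np.atleast_1d(np.asarray(lags, dtype=int))
    if lags.size == 0:
        raise ValueError("empty lag set")
    T = pos.shape[1]
    if T < 2:
        raise ValueError("need at least 2 samples")
    if np.any(lags < 0) or np.any(lags >= T):
        raise ValueError("lags must lie within the series length")
    out = np.empty(lags.shape, dtype=float)
    for i, lag in enumerate(lags):
        if lag == 0:
            out[i] = 0.0
            continue
        d = pos[:, lag:, :] - pos[:, :-lag, :]
        out[i] = np.nanmean(np.sum(d * d, axis=-1))
    return out


def velocities(positions: np.ndarray, window: int = 1, dt: float = 1.0) -> np.ndarray:
    """Finite-difference velocities over ``window`` samples: (R[t+w]-R[t])/(w dt)."""
    pos = _as_ensemble(positions)
    if window < 1 or pos.shape[1] <= window:
        raise ValueError("window must be >= 1 and shorter than the series")
    v = (pos[:, window:, :] - pos[:, :-window, :]) / (window * dt)
    return v if np.asarray(positions).ndim == 3 else v[0]


def orientations(vel: np.ndarray) -> np.ndarray:
    """Unit heading vectors v/||v||; NaN where the speed vanishes."""
    v = np.asarray(vel, dtype=float)
    speed = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = v / speed
    u[np.broadcast_to(speed == 0, u.shape)] = np.nan
    return u


def vacf(vel: np.ndarray, lags) -> np.ndarray:
    """Normalized velocity autocorrelation C(tau) = <u(t+tau).u(t)>, C(0)=1."""
    v = np.asarray(vel, dtype=float)
    if v.ndim == 2:
        v = v[None]
    u = orientations(v)
    if np.all(np.isnan(u)):
        raise ValueError("all velocities vanish; orientation undefined")
    lags = np.atleast_1d(np.asarray(lags, dtype=int))
    T = u.shape[1]
    if np.any(lags < 0) or np.any(lags >= T):
        raise ValueError("lags must lie within the series length")
    out = np.empty(lags.shape, dtype=float)
    for i, lag in enumerate(lags):
        if lag == 0:
            prod = np.sum(u * u, axis=-1)
        else:
            prod = np.sum(u[:, lag:, :] * u[:, :-lag, :], axis=-1)
        out[i] = np.nanmean(prod)
    return out


def furth_msd(tau: np.ndarray, v: float, tau_p: float) -> np.ndarray:
    """2-D persistent-random-walk MSD: 2 v^2 tau_p [tau - tau_p(1 - e^(-tau/tau_p))]."""
    tau = np.asarray(tau, dtype=float)
    return 2.0 * v * v * tau_p * (tau - tau_p * (1.0 - np.exp(-tau / tau_p)))


@dataclass
class PRWFit:
    """Persistent-random-walk fit result (speed, persistence time, diagnostics)."""
    v: float
    tau_p: float
    converged: bool
    message: str = ""
    cov: np.ndarray | None = None


def fit_prw(lags: np.ndarray, msd_curve: np.ndarray) -> PRWFit:
    """Least-squares fit of the Fuerth MSD form; never fails silently.

    Uses relative weighting so the ballistic and diffusive regimes count
    equally.  Non-convergence is flagged on the returned object.
    """
    lags = np.asarray(lags, dtype=float)
    y = np.asarray(msd_curve, dtype=float)
    ok = (lags > 0) & np.isfinite(y) & (y > 0)
    lags, y = lags[ok], y[ok]
    if lags.size < 5:
        return PRWFit(np.nan, np.nan, False, "need >= 5 positive lag points")
    v0 = np.sqrt(y[0]) / lags[0]
    tp0 = lags[len(lags) // 2]
    try:
        popt, pcov = optimize.curve_fit(
            furth_msd, lags, y, p0=(max(v0, 1e-9), max(tp0, 1e-6)),
            sigma=y, bounds=([1e-12, 1e-9], [np.inf, np.inf]), maxfev=20000)
    except Exception as exc:  # noqa: BLE001 - surfaced as a flagged result
        return PRWFit(np.nan, np.nan, False, f"fit failed: {exc}")
    return PRWFit(float(popt[0]), float(popt[1]), True, "", pcov)


def correlation_time(lags: np.ndarray, C: np.ndarray,
                     tail_tau: float | None = None,
                     cutoff: float = 0.05) -> float:
    """Correlation time as the integral of an autocorrelation function.

    Integrates C over the lags up to its first drop below ``cutoff`` and
    adds an exponential-tail correction ``C_last * tail_tau`` when a tail
    estimate is supplied.  For an exponential decay this equals the time
    constant, and it is robust to the slow non-exponential tails that
    log-slope fits overweight.
    """
    lags = np.asarray(lags, dtype=float)
    C = np.asarray(C, dtype=float)
    below = np.flatnonzero(C < cutoff)
    k = int(below[0]) if below.size else len(C)
    if k < 2:
        raise ValueError("autocorrelation drops below cutoff immediately")
    tau = float(np.trapezoid(C[:k], lags[:k]))
    if k < len(C) and tail_tau is not None and C[k - 1] > 0:
        tau += float(C[k - 1]) * float(tail_tau)
    return tau


def msd_loglog_slope(lags: np.ndarray, msd_curve: np.ndarray,
                     mask: np.ndarray | None = None) -> float:
    """Log-log power-law exponent of the MSD over the (masked) lag range."""
    lags = np.asarray(lags, dtype=float)
    y = np.asarray(msd_curve, dtype=float)
    if mask is None:
        mask = np.ones(lags.shape, dtype=bool)
    mask = mask & (lags > 0) & (y > 0)
    if mask.sum() < 2:
        raise ValueError("need >= 2 points for a slope")
    res = stats.linregress(np.log(lags[mask]), np.log(y[mask]))
    return float(res.slope)


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def shape_metrics(config, cell_id: int):
    """Aspect ratio l+/l- and principal axes from the gyration tensor.

    Returns ``(ratio, (l_plus, l_minus), axes)`` where ``axes`` columns are
    the principal directions (major first).  Degenerate (collinear or
    sub-3-site) cells report ``ratio = inf``.
    """
    sites = config.sites_of(cell_id)
    if len(sites) == 0:
        raise ValueError(f"cell {cell_id} is empty")
    xs = config.ux[sites] - config.ux[sites].mean()
    ys = config.uy[sites] - config.uy[sites].mean()
    cov = np.array([[np.mean(xs * xs), np.mean(xs * ys)],
                    [np.mean(xs * ys), np.mean(ys * ys)]])
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    l_plus = float(np.sqrt(max(evals[0], 0.0)))
    l_minus = float(np.sqrt(max(evals[1], 0.0)))
    if len(sites) < 3 or l_minus < 1e-9:
        return np.inf, (l_plus, l_minus), evecs
    return l_plus / l_minus, (l_plus, l_minus), evecs


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

def trajectory_curvature(positions: np.ndarray, window: int = 10,
                         dt: float = 1.0) -> float:
    """Mean trajectory curvature <c> = <|d theta / d s|> of the smoothed tangent.

    The tangent is block-averaged over ``window`` samples (default: the
    10-MCS intrinsic timescale) before differentiating, and zero-length
    segments are skipped.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("positions must be (T, 2)")
    T = pos.shape[0]
    nblk = (T - 1) // window
    if nblk < 3:
        raise ValueError("need >= 3 smoothed samples")
    disp = np.array([pos[(i + 1) * window] - pos[i * window] for i in range(nblk)])
    lens = np.linalg.norm(disp, axis=1)
    keep = lens > 0
    disp, lens = disp[keep], lens[keep]
    if len(disp) < 2:
        raise ValueError("trajectory has no net motion")
    theta = np.arctan2(disp[:, 1], disp[:, 0])
    dtheta = np.angle(np.exp(1j * np.diff(theta)))
    ds = 0.5 * (lens[1:] + lens[:-1])
    return float(np.mean(np.abs(dtheta) / ds))


# ---------------------------------------------------------------------------
# Collective rotation
# ---------------------------------------------------------------------------

def cluster_angular_velocity(positions: np.ndarray, vel: np.ndarray) -> np.ndarray:
    """Signed cluster angular velocity omega(t), counter-clockwise positive.

    ``positions`` and ``vel`` are (T, C, 2); both are taken relative to the
    instantaneous population means, and omega is the population average of
    ez . (R_rel x v_rel) / ||R_rel||^2, excluding cells at the centroid.
    """
    R = np.asarray(positions, dtype=float)
    V = np.asarray(vel, dtype=float)
    if R.shape != V.shape or R.ndim != 3 or R.shape[1] < 2:
        raise ValueError("need matching (T, C>=2, 2) position and velocity arrays")
    Rrel = R - np.nanmean(R, axis=1, keepdims=True)
    Vrel = V - np.nanmean(V, axis=1, keepdims=True)
    r2 = np.sum(Rrel * Rrel, axis=-1)
    cross = Rrel[..., 0] * Vrel[..., 1] - Rrel[..., 1] * Vrel[..., 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(r2 > 0, cross / r2, np.nan)
    return np.nanmean(w, axis=1)


def rotation_stats(omega: np.ndarray, perim_mean: np.ndarray | None = None,
                   signed: bool = False):
    """(<|omega|>, sigma_omega, sigma_P) of a rotation time series.

    ``sigma_omega`` is the standard deviation of |omega| (of signed omega
    if ``signed``); ``sigma_P`` the standard deviation of the
    population-mean perimeter series (NaN if not given).  Replicate axes
    may simply be concatenated/stacked — statistics pool everything.
    """
    w = np.abs(np.asarray(omega, dtype=float).ravel())
    w = w[np.isfinite(w)]
    if w.size < 2:
        raise ValueError("need an omega series of length >= 2")
    sw = (np.nanstd(np.asarray(omega, dtype=float)) if signed
          else float(np.std(w)))
    sp = np.nan
    if perim_mean is not None:
        p = np.asarray(perim_mean, dtype=float).ravel()
        sp = float(np.nanstd(p))
    return float(np.mean(w)), float(sw), sp


# ---------------------------------------------------------------------------
# Tissue fields
# ---------------------------------------------------------------------------

def cell_pressure(area, perim, eps_ref, kA_eff, kP_eff) -> np.ndarray:
    """Per-cell isotropic stress from a virtual uniform dilation (tension > 0).

    Pi = 2 kA_eff A + kP_eff P^2 / A - eps_ref: the area-derivative of the
    cell energy under a virtual uniform dilation with P ~ sqrt(A) shape
    scaling.  A stretched cell (A above its solitary equilibrium) pulls on
    its neighbors, Pi > 0 (tension); a compressed cell pushes, Pi < 0
    (pressure); ~0 at the solitary equilibrium area.

    ``eps_ref`` is the polarization energy per site used as the adhesion
    reference — normally the rest value eps0, so the map shows the elastic
    stress transmitted through the sheet rather than each cell's current
    polarization level (using the instantaneous mean field instead makes
    strongly polarized leading-edge cells look artificially slack).
    ``perim`` is the boundary-edge count; the contour-length conversion of
    the perimeter energy is applied internally.
    """
    from .hexgrid import EDGE_LENGTH
    A = np.asarray(area, dtype=float)
    P = np.asarray(perim, dtype=float) * EDGE_LENGTH
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(A > 0,
                        2.0 * np.asarray(kA_eff, float) * A
                        + np.asarray(kP_eff, float) * P * P / np.where(A > 0, A, 1)
                        - np.asarray(eps_ref, float),
                        np.nan)


def _bin_index(lattice, x_edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ix = np.digitize(lattice.cx, x_edges) - 1
    valid = (ix >= 0) & (ix < len(x_edges) - 1)
    return ix, valid


def density_profile(lattice, owner: np.ndarray, x_edges: np.ndarray) -> np.ndarray:
    """Occupied-site fraction per x-bin (y-averaged cell density)."""
    ix, valid = _bin_index(lattice, x_edges)
    nb = len(x_edges) - 1
    per_bin = np.bincount(ix[valid], minlength=nb).astype(float)
    occ = np.bincount(ix[valid & (owner > 0)], minlength=nb).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(per_bin > 0, occ / np.where(per_bin > 0, per_bin, 1), np.nan)
    return out


def stress_profile(lattice, owner: np.ndarray, x_edges: np.ndarray,
                   pi_per_cell: np.ndarray) -> np.ndarray:
    """y-averaged sigma_xx per x-bin: per-cell Pi spread over the cell's sites.

    Bins containing lattice sites but no cells read 0 (stress-free vacuum);
    bins with no lattice sites are NaN (missing).
    """
    ix, valid = _bin_index(lattice, x_edges)
    nb = len(x_edges) - 1
    per_bin = np.bincount(ix[valid], minlength=nb).astype(float)
    sel = valid & (owner > 0)
    pi_site = np.asarray(pi_per_cell, dtype=float)[owner[sel]]
    tot = np.bincount(ix[sel], weights=np.nan_to_num(pi_site), minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(per_bin > 0, tot / np.where(per_bin > 0, per_bin, 1), np.nan)
    return out


def velocity_profile(lattice, owner: np.ndarray, x_edges: np.ndarray,
                     vx_per_cell: np.ndarray) -> np.ndarray:
    """Occupancy-weighted mean cell velocity x-component per x-bin (NaN if empty)."""
    ix, valid = _bin_index(lattice, x_edges)
    nb = len(x_edges) - 1
    sel = valid & (owner > 0)
    vx_site = np.asarray(vx_per_cell, dtype=float)[owner[sel]]
    fin = np.isfinite(vx_site)
    num = np.bincount(ix[sel][fin], weights=vx_site[fin], minlength=nb)
    den = np.bincount(ix[sel][fin], minlength=nb).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)


@dataclass
class Kymograph:
    """Space-time maps of y-averaged tissue fields along the expansion axis."""
    x_edges: np.ndarray
    times: np.ndarray
    density: np.ndarray      # (T, n_bins)
    sigma_xx: np.ndarray
    vx: np.ndarray

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])


def tissue_kymographs(times, density_rows, sigma_rows, vx_rows, x_edges) -> Kymograph:
    """Assemble per-record profiles into a :class:`Kymograph`."""
    return Kymograph(np.asarray(x_edges, float), np.asarray(times, float),
                     np.vstack(density_rows), np.vstack(sigma_rows),
                     np.vstack(vx_rows))


def first_crossing_times(kymo_field: np.ndarray, times: np.ndarray,
                         threshold: float = 0.0) -> np.ndarray:
    """Per-bin first time the field exceeds ``threshold`` (NaN if never)."""
    T, nb = kymo_field.shape
    out = np.full(nb, np.nan)
    for j in range(nb):
        above = np.flatnonzero(kymo_field[:, j] > threshold)
        if above.size:
            out[j] = times[above[0]]
    return out


# ---------------------------------------------------------------------------
# Fronts
# ---------------------------------------------------------------------------

def front_profile(lattice, owner: np.ndarray, side: str = "right") -> np.ndarray:
    """Leading edge h(y): outermost occupied x per lattice row (NaN if empty row)."""
    occ = np.flatnonzero(owner > 0)
    h = np.full(lattice.n_rows, np.nan)
    if occ.size == 0:
        return h
    rows = lattice.r[occ]
    xs = lattice.cx[occ]
    if side == "right":
        h2 = np.full(lattice.n_rows, -np.inf)
        np.maximum.at(h2, rows, xs)
        h = np.where(np.isfinite(h2), h2, np.nan)
    elif side == "left":
        h2 = np.full(lattice.n_rows, np.inf)
        np.minimum.at(h2, rows, xs)
        h = np.where(np.isfinite(h2), h2, np.nan)
    else:
        raise ValueError("side must be 'left' or 'right'")
    return h


def roughness_of_profile(h: np.ndarray) -> float:
    """Front roughness w = std of the edge height profile (NaN rows excluded)."""
    h = np.asarray(h, dtype=float)
    h = h[np.isfinite(h)]
    if h.size == 0:
        raise ValueError("no tissue rows in profile")
    return float(np.std(h))


def front_roughness(config, side: str = "right") -> float:
    """Roughness of a tissue front directly from a configuration."""
    return roughness_of_profile(front_profile(config.lattice, config.owner, side))


# ---------------------------------------------------------------------------
# Oscillations
# ---------------------------------------------------------------------------

def dominant_period(series: np.ndarray, dt: float = 1.0,
                    detrend: str = "linear") -> float:
    """Dominant oscillation period of a time series via the periodogram.

    The series is detrended (linear by default) and the period of the
    highest-power finite-frequency component is returned, restricted to
    periods shorter than half the record so trends do not masquerade as
    oscillations.
    """
    y = np.asarray(series, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 8:
        raise ValueError("series too short for a periodogram")
    freqs, power = signal.periodogram(y, fs=1.0 / dt, detrend=detrend)
    span = y.size * dt
    ok = (freqs > 2.0 / span)
    if not np.any(ok):
        raise ValueError("no admissible frequencies")
    f = freqs[ok][np.argmax(power[ok])]
    return float(1.0 / f)
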