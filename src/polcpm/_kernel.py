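"""Numba kernels for the Monte-Carlo-step loop.

All state lives in flat numpy arrays owned by :class:`polcpm.engine.Simulation`;
the functions here mutate them in place.  Elementary events are drawn
uniformly from the live set of directed boundary pairs (source, target) —
lattice-neighbor pairs whose owners differ, neither owner a wall, at least
one a cell.  The pair set is maintained incrementally: a flip at the target
site only affects the <= 6 undirected edges incident on it.

Acceptance uses the Metropolis rule at temperature kBT, optionally with a
Metropolis-Hastings factor n_pairs(before)/n_pairs(after) compensating the
state-dependent proposal distribution, so that with feedback disabled
(mu = 0) the chain samples the Boltzmann distribution exactly.

Randomness comes from numba's internal np.random state; seed it through
:func:`seed_rng` before a run.
"""

import numpy as np
from numba import njit

# phi application modes
PHI_ADDITIVE = 0
PHI_MULTIPLICATIVE = 1

# (hexagon side length)^2: converts squared boundary-edge counts to squared
# contour length in the perimeter energy
EDGE_LEN2 = 1.0 / 3.0


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def pair_valid(owner, neigh, a, d):
    b = neigh[a, d]
    if b < 0:
        return False
    oa = owner[a]
    ob = owner[b]
    return oa >= 0 and ob >= 0 and oa != ob


@njit(cache=True)
def rebuild_pairs(owner, neigh, pair_list, pair_pos):
    """Enumerate all directed boundary pairs from scratch; returns the count."""
    pair_pos[:] = -1
    n = 0
    for a in range(owner.shape[0]):
        for d in range(6):
            if pair_valid(owner, neigh, a, d):
                pid = a * 6 + d
                pair_pos[pid] = n
                pair_list[n] = pid
                n += 1
    return n


@njit(cache=True)
def eval_event(owner, eps, phi, phi_mode, neigh, area, perim, kA, kP,
               B, dB, D, fric_mode, a, b):
    """Incremental energy difference of owner[a] conquering site b.

    Returns (dH, dP_gain, dP_lose, d_npairs, m_fwd, m_rev): the event
    energy including dissipative friction/substrate terms, the perimeter
    increments of the gaining and losing cells, the change in the
    directed-pair count, and the proposal-channel multiplicities (number
    of neighbors of b owned by the conqueror / by the current owner) used
    in the Metropolis-Hastings correction.

    ``fric_mode`` selects when the dissipative rupture cost dB applies to a
    destroyed contact edge: 0 = only on true separation (target site
    becomes empty), 1 = on every destroyed contact edge (junction
    migration included).
    """
    g = owner[a]
    l = owner[b]
    dPg = 0
    dPl = 0
    created = 0
    destroyed = 0
    dnp = 0
    m_fwd = 0
    m_rev = 0
    for d in range(6):
        ns = neigh[b, d]
        if ns < 0:
            continue
        w = owner[ns]
        if w == g:
            m_fwd += 1
        if w == l:
            m_rev += 1
        if w == g:
            dPg -= 1
        else:
            dPg += 1
        if w == l:
            dPl += 1
        else:
            dPl -= 1
        if l > 0 and w > 0 and w != l:
            destroyed += 1
        if g > 0 and w > 0 and w != g:
            created += 1
        if w >= 0:
            before = 1 if w != l else 0
            after = 1 if w != g else 0
            dnp += 2 * (after - before)
    dH = -B * created + B * destroyed
    if dB > 0.0 and destroyed > 0 and (fric_mode == 1 or g == 0):
        dH += dB * destroyed
    if g > 0:
        ag = area[g]
        pg = perim[g]
        dH += kA[g] * ((ag + 1.0) ** 2 - ag * ag) \
            + kP[g] * EDGE_LEN2 * ((pg + dPg) * 1.0 * (pg + dPg) - pg * 1.0 * pg)
        if phi_mode == PHI_MULTIPLICATIVE:
            dH -= eps[a] * phi[b]
        else:
            dH -= eps[a] + phi[b]
    if l > 0:
        al = area[l]
        pl = perim[l]
        dH += kA[l] * ((al - 1.0) ** 2 - al * al) \
            + kP[l] * EDGE_LEN2 * ((pl + dPl) * 1.0 * (pl + dPl) - pl * 1.0 * pl)
        if phi_mode == PHI_MULTIPLICATIVE:
            dH += eps[b] * phi[b]
        else:
            dH += eps[b] + phi[b]
        dH += D
    return dH, dPg, dPl, dnp, m_fwd, m_rev


@njit(cache=True)
def removal_keeps_connected(owner, neigh, cid, b, area_l, visited, stamp, queue):
    """True if cell cid stays 6-connected after losing site b.

    Local ring check on the cyclically ordered neighbors of b; flood-fill
    fallback when the owned neighbors form more than one arc.
    """
    arcs = 0
    n5 = neigh[b, 5]
    prev_owned = n5 >= 0 and owner[n5] == cid
    start = -1
    for d in range(6):
        n = neigh[b, d]
        owned = n >= 0 and owner[n] == cid
        if owned:
            if start < 0:
                start = n
            if not prev_owned:
                arcs += 1
        prev_owned = owned
    if arcs <= 1:
        return True
    stamp[0] += 1
    st = stamp[0]
    visited[b] = st
    visited[start] = st
    queue[0] = start
    head = 0
    tail = 1
    count = 1
    while head < tail:
        cur = queue[head]
        head += 1
        for d in range(6):
            n = neigh[cur, d]
            if n >= 0 and owner[n] == cid and visited[n] != st:
                visited[n] = st
                queue[tail] = n
                tail += 1
                count += 1
    return count == area_l - 1


@njit(cache=True)
def record_feedback_at(owner, F, nc, nr, px, py, offs_even, offs_odd, b, g, l):
    """Integer regulatory increments within radius R of an accepted event at b.

    +1 on sites of the gaining cell g, -1 on sites of the losing cell l
    (either may be absent, id 0).  The disk offsets are precomputed for
    both row parities.
    """
    q0 = b % nc
    r0 = b // nc
    offs = offs_odd if (r0 & 1) else offs_even
    for k in range(offs.shape[0]):
        qt = q0 + offs[k, 0]
        rt = r0 + offs[k, 1]
        if px:
            qt = qt % nc
        elif qt < 0 or qt >= nc:
            continue
        if py:
            rt = rt % nr
        elif rt < 0 or rt >= nr:
            continue
        s2 = rt * nc + qt
        w = owner[s2]
        if g > 0 and w == g:
            F[s2] += 1
        elif l > 0 and w == l:
            F[s2] -= 1


@njit(cache=True)
def polarization_update(owner, eps, F, deps_eff, eps0, mu):
    """Once-per-MCS relaxation of eps toward the F-sign-selected target; resets F."""
    for s in range(owner.shape[0]):
        o = owner[s]
        if o > 0:
            if F[s] > 0:
                tgt = eps0 + 0.5 * deps_eff[o]
            elif F[s] < 0:
                tgt = eps0 - 0.5 * deps_eff[o]
            else:
                tgt = eps0
            eps[s] += mu * (tgt - eps[s])
        F[s] = 0


@njit(cache=True)
def _update_pairs_around(owner, neigh, pair_list, pair_pos, n_pairs, b):
    """Revalidate the <= 12 directed pairs on edges incident to site b."""
    for d2 in range(6):
        n2 = neigh[b, d2]
        if n2 < 0:
            continue
        for which in range(2):
            if which == 0:
                s = b
                dd = d2
            else:
                s = n2
                dd = (d2 + 3) % 6
            pid = s * 6 + dd
            valid = pair_valid(owner, neigh, s, dd)
            pos = pair_pos[pid]
            if valid and pos < 0:
                pair_pos[pid] = n_pairs
                pair_list[n_pairs] = pid
                n_pairs += 1
            elif (not valid) and pos >= 0:
                last = pair_list[n_pairs - 1]
                pair_list[pos] = last
                pair_pos[last] = pos
                pair_pos[pid] = -1
                n_pairs -= 1
    return n_pairs


@njit(cache=True)
def run_mcs(n_mcs,
            owner, eps, F, phi, phi_mode,
            neigh, cx, cy, width, height, px, py,
            ux, uy, area, perim, comx, comy,
            kA, kP, deps_eff,
            eps0, mu, B, dB, D, fric_mode, kBT, balanced,
            offs_even, offs_odd, nc, nr,
            pair_list, pair_pos, n_pairs,
            visited, stamp, queue):
    """Run ``n_mcs`` Monte Carlo steps in place; returns the live pair count.

    One MCS performs N_attempt propose/evaluate/accept cycles, where
    N_attempt is the directed-boundary-pair count frozen at the MCS start
    (draws use the live set), then applies the polarization update.
    """
    half_w = 0.5 * width
    half_h = 0.5 * height
    for _ in range(n_mcs):
        n_att = n_pairs
        for _att in range(n_att):
            if n_pairs == 0:
                break
            idx = int(np.random.random() * n_pairs)
            if idx >= n_pairs:
                idx = n_pairs - 1
            pid = pair_list[idx]
            a = pid // 6
            d = pid % 6
            b = neigh[a, d]
            g = owner[a]
            l = owner[b]
            if l > 0:
                if area[l] <= 1:
                    continue  # cell annihilation disallowed
                if not removal_keeps_connected(owner, neigh, l, b, area[l],
                                               visited, stamp, queue):
                    continue  # fragmenting moves rejected
            dH, dPg, dPl, dnp, m_fwd, m_rev = eval_event(
                owner, eps, phi, phi_mode, neigh, area, perim, kA, kP,
                B, dB, D, fric_mode, a, b)
            logp = -dH / kBT
            if balanced:
                if n_pairs + dnp <= 0 or m_rev == 0:
                    continue  # reverse proposal impossible: reject
                logp += np.log(m_rev * n_pairs / (m_fwd * (n_pairs + dnp)))
            if logp < 0.0 and np.random.random() >= np.exp(logp):
                continue
            # --- apply the flip ---
            if l > 0:
                area[l] -= 1
                perim[l] += dPl
                comx[l] -= ux[b]
                comy[l] -= uy[b]
            owner[b] = g
            if g > 0:
                dx = cx[b] - cx[a]
                dy = cy[b] - cy[a]
                if px:
                    if dx > half_w:
                        dx -= width
                    elif dx < -half_w:
                        dx += width
                if py:
                    if dy > half_h:
                        dy -= height
                    elif dy < -half_h:
                        dy += height
                ux[b] = ux[a] + dx
                uy[b] = uy[a] + dy
                area[g] += 1
                perim[g] += dPg
                comx[g] += ux[b]
                comy[g] += uy[b]
                eps[b] = eps[a]
            else:
                eps[b] = 0.0
            F[b] = 0
            n_pairs = _update_pairs_around(owner, neigh, pair_list, pair_pos,
                                           n_pairs, b)
            record_feedback_at(owner, F, nc, nr, px, py, offs_even, offs_odd,
                               b, g, l)
        polarization_update(owner, eps, F, deps_eff, eps0, mu)
    return n_pairs
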