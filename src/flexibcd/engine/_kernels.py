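"""Numba kernels for the BCD propagator.

Layout of the mutable state (all preallocated by the wrapper):

``pos``        (N, 3) wrapped coordinates in [0, L)
``img``        (N, 3) integer periodic-image vectors; ``pos + img*L`` gives
               coordinates that are *consistent within each bonded cluster*
               (bonded pairs differ by their minimum-image displacement).
``adj/deg``    fixed-width adjacency lists of the irreversible bond graph
``parent``     union-find forest over particles; clusters are its trees
``csize``      cluster size, valid at roots
``head_m/next_m/tail_m``  intrusive singly-linked member lists, per root
``span``       (N, 3) per-root wrap-closure flags: a bond that closes a
               cycle with nonzero net image shift along axis k marks the
               cluster as spanning axis k (percolation)
``rouse``      (N, 3) per-root net displacement of accepted monomer moves
               in the current sweep; sets the Zimm direction
``chead/cnext/cprev``  doubly-linked cell lists for O(1) particle moves

The RNG is an explicit xorshift128+ stream carried in a 2-element uint64
array, so trajectories are reproducible independent of numba internals.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_BONDS = 32

# status codes returned by run_sweeps
OK = 0
ERR_ADJ_OVERFLOW = 1


# ---------------------------------------------------------------- RNG

@njit(cache=True, inline="always")
def _rng_next(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return state[0] + state[1]


@njit(cache=True, inline="always")
def _rng_uniform(state):
    return (_rng_next(state) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True, inline="always")
def _rng_below(state, n):
    return int(_rng_uniform(state) * n) % n


@njit(cache=True)
def seed_rng(seed):
    """Expand a small integer seed into a full xorshift128+ state (splitmix64)."""
    state = np.empty(2, dtype=np.uint64)
    x = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        z = x
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = z ^ (z >> np.uint64(31))
        x += np.uint64(0x9E3779B97F4A7C15)
    if state[0] == 0 and state[1] == 0:
        state[0] = np.uint64(1)
    return state


@njit(cache=True, inline="always")
def _rand_unit_vector(state, out):
    # Marsaglia (1972) rejection on the unit disc
    while True:
        u = 2.0 * _rng_uniform(state) - 1.0
        v = 2.0 * _rng_uniform(state) - 1.0
        s = u * u + v * v
        if s < 1.0:
            f = 2.0 * np.sqrt(1.0 - s)
            out[0] = u * f
            out[1] = v * f
            out[2] = 1.0 - 2.0 * s
            return


# ---------------------------------------------------------------- cells

@njit(cache=True, inline="always")
def _cell_of(x, y, z, edge, ncell):
    cx = int(x / edge)
    cy = int(y / edge)
    cz = int(z / edge)
    if cx >= ncell:
        cx = ncell - 1
    if cy >= ncell:
        cy = ncell - 1
    if cz >= ncell:
        cz = ncell - 1
    return (cx * ncell + cy) * ncell + cz


@njit(cache=True)
def build_cells(pos, L, ncell, chead, cnext, cprev, ccell):
    edge = L / ncell
    chead[:] = -1
    n = pos.shape[0]
    for i in range(n):
        c = _cell_of(pos[i, 0], pos[i, 1], pos[i, 2], edge, ncell)
        ccell[i] = c
        cnext[i] = chead[c]
        cprev[i] = -1
        if chead[c] >= 0:
            cprev[chead[c]] = i
        chead[c] = i


@njit(cache=True, inline="always")
def _cell_move(i, cnew, chead, cnext, cprev, ccell):
    cold = ccell[i]
    if cold == cnew:
        return
    # unlink
    if cprev[i] >= 0:
        cnext[cprev[i]] = cnext[i]
    else:
        chead[cold] = cnext[i]
    if cnext[i] >= 0:
        cprev[cnext[i]] = cprev[i]
    # insert at head of cnew
    ccell[i] = cnew
    cnext[i] = chead[cnew]
    cprev[i] = -1
    if chead[cnew] >= 0:
        cprev[chead[cnew]] = i
    chead[cnew] = i


# ---------------------------------------------------------------- union-find

@njit(cache=True, inline="always")
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True, inline="always")
def _min_image_scalar(d, L):
    # valid for |d| < 1.5 L, always true for differences of wrapped coords
    if d >= 0.5 * L:
        return d - L
    if d < -0.5 * L:
        return d + L
    return d


@njit(cache=True, inline="always")
def _overlap_at(i, x, y, z, pos, L, edge, ncell, sigma2_lo,
                chead, cnext, skip_root, parent, use_skip):
    """True if a particle at (x,y,z) would overlap any particle other than i
    (and, when use_skip, other than members of cluster skip_root)."""
    cx = int(x / edge)
    cy = int(y / edge)
    cz = int(z / edge)
    for ox in range(-1, 2):
        gx = (cx + ox) % ncell
        for oy in range(-1, 2):
            gy = (cy + oy) % ncell
            for oz in range(-1, 2):
                gz = (cz + oz) % ncell
                q = chead[(gx * ncell + gy) * ncell + gz]
                while q >= 0:
                    if q != i:
                        if use_skip and _find(parent, q) == skip_root:
                            q = cnext[q]
                            continue
                        dx = _min_image_scalar(x - pos[q, 0], L)
                        dy = _min_image_scalar(y - pos[q, 1], L)
                        dz = _min_image_scalar(z - pos[q, 2], L)
                        if dx * dx + dy * dy + dz * dz < sigma2_lo:
                            return True
                    q = cnext[q]
    return False


@njit(cache=True)
def _merge_or_flag(p, q, pos, img, parent, csize, head_m, next_m, tail_m,
                   span, rouse, spec_span, gel_sweep, species, L, sweep):
    """Union the clusters of newly bonded p and q, keeping periodic-image
    consistency; a same-cluster bond with net image mismatch marks spanning."""
    rp = _find(parent, p)
    rq = _find(parent, q)
    d0 = pos[p, 0] - pos[q, 0]
    d1 = pos[p, 1] - pos[q, 1]
    d2 = pos[p, 2] - pos[q, 2]
    del0 = np.int64(np.rint(d0 / L))
    del1 = np.int64(np.rint(d1 / L))
    del2 = np.int64(np.rint(d2 / L))
    if rp == rq:
        m0 = img[p, 0] - img[q, 0] + del0
        m1 = img[p, 1] - img[q, 1] + del1
        m2 = img[p, 2] - img[q, 2] + del2
        newly = False
        if m0 != 0 and not span[rp, 0]:
            span[rp, 0] = True
            newly = True
        if m1 != 0 and not span[rp, 1]:
            span[rp, 1] = True
            newly = True
        if m2 != 0 and not span[rp, 2]:
            span[rp, 2] = True
            newly = True
        if newly:
            sp = species[p]
            if spec_span[sp] == 0:
                spec_span[sp] = 1
                gel_sweep[sp] = sweep
        return
    # shift the smaller cluster's image vectors so that unwrapped
    # coordinates are consistent across the new bond
    sh0 = img[p, 0] + del0 - img[q, 0]
    sh1 = img[p, 1] + del1 - img[q, 1]
    sh2 = img[p, 2] + del2 - img[q, 2]
    if csize[rq] <= csize[rp]:
        small, big = rq, rp
    else:
        small, big = rp, rq
        sh0, sh1, sh2 = -sh0, -sh1, -sh2
    if sh0 != 0 or sh1 != 0 or sh2 != 0:
        m = head_m[small]
        while m >= 0:
            img[m, 0] += sh0
            img[m, 1] += sh1
            img[m, 2] += sh2
            m = next_m[m]
    parent[small] = big
    csize[big] += csize[small]
    next_m[tail_m[big]] = head_m[small]
    tail_m[big] = tail_m[small]
    for k in range(3):
        if span[small, k]:
            span[big, k] = True
        rouse[big, k] += rouse[small, k]


@njit(cache=True)
def _bond_pass(pos, img, species, deg, adj, parent, csize, head_m, next_m,
               tail_m, span, rouse, spec_span, gel_sweep, moved,
               chead, cnext, L, edge, ncell, bond2_hi, sweep):
    """Bond every unbonded same-species pair within the well range.

    Only particles flagged as moved since the previous pass are scanned:
    a pair can newly enter the well only if at least one member moved.
    The flags are cleared on exit (Zimm moves re-set them afterwards, so
    they carry into the next sweep's pass).
    """
    n = pos.shape[0]
    for p in range(n):
        if moved[p] == 0:
            continue
        cx = int(pos[p, 0] / edge)
        cy = int(pos[p, 1] / edge)
        cz = int(pos[p, 2] / edge)
        sp = species[p]
        for ox in range(-1, 2):
            gx = (cx + ox) % ncell
            for oy in range(-1, 2):
                gy = (cy + oy) % ncell
                for oz in range(-1, 2):
                    gz = (cz + oz) % ncell
                    q = chead[(gx * ncell + gy) * ncell + gz]
                    while q >= 0:
                        if q != p and species[q] == sp:
                            already = False
                            for k in range(deg[p]):
                                if adj[p, k] == q:
                                    already = True
                                    break
                            if not already:
                                dx = _min_image_scalar(pos[p, 0] - pos[q, 0], L)
                                dy = _min_image_scalar(pos[p, 1] - pos[q, 1], L)
                                dz = _min_image_scalar(pos[p, 2] - pos[q, 2], L)
                                if dx * dx + dy * dy + dz * dz <= bond2_hi:
                                    if deg[p] >= MAX_BONDS or deg[q] >= MAX_BONDS:
                                        return ERR_ADJ_OVERFLOW
                                    adj[p, deg[p]] = q
                                    deg[p] += 1
                                    adj[q, deg[q]] = p
                                    deg[q] += 1
                                    _merge_or_flag(p, q, pos, img, parent, csize,
                                                   head_m, next_m, tail_m, span,
                                                   rouse, spec_span, gel_sweep,
                                                   species, L, sweep)
                        q = cnext[q]
    for p in range(n):
        moved[p] = 0
    return OK


@njit(cache=True)
def run_sweeps(pos, img, species, deg, adj, parent, csize, head_m, next_m,
               tail_m, span, rouse, move_credit, moved,
               chead, cnext, cprev, ccell,
               spec_span, gel_sweep, rng,
               L, ncell, sigma, bond_range, s, p_flex_arr,
               zimm_enabled, deterministic_gate, bonding_enabled,
               n_sweeps, sweep_start):
    """Advance the state by ``n_sweeps`` sweeps; returns a status code.

    One sweep = N gated monomer-move attempts on uniformly random
    particles, then a bond-formation pass, then one Zimm translation
    attempt per non-spanning multi-particle cluster.
    """
    n = pos.shape[0]
    edge = L / ncell
    sigma2_lo = sigma * sigma - 1e-12
    bond2_hi = bond_range * bond_range + 1e-12
    dirv = np.empty(3, dtype=np.float64)
    # the incremental bond pass is only valid against a fully scanned
    # baseline: flag everything before the first sweep of a batch
    for i in range(n):
        moved[i] = 1
    for sweep_i in range(n_sweeps):
        # label events with the index of the state the sweep produces
        sweep = sweep_start + sweep_i + 1
        # reset per-sweep Rouse accumulators (roots only are read)
        for i in range(n):
            rouse[i, 0] = 0.0
            rouse[i, 1] = 0.0
            rouse[i, 2] = 0.0

        # ---- monomer moves -------------------------------------------
        for _ in range(n):
            p = _rng_below(rng, n)
            if deg[p] > 0:
                pf = p_flex_arr[species[p]]
                if deterministic_gate:
                    move_credit[p] += pf
                    if move_credit[p] >= 1.0 - 1e-12:
                        move_credit[p] -= 1.0
                    else:
                        continue
                else:
                    if pf < 1.0 and _rng_uniform(rng) >= pf:
                        continue
            _rand_unit_vector(rng, dirv)
            nx = pos[p, 0] + s * dirv[0]
            ny = pos[p, 1] + s * dirv[1]
            nz = pos[p, 2] + s * dirv[2]
            # wrap, tracking image increments
            ix = np.int64(np.floor(nx / L))
            iy = np.int64(np.floor(ny / L))
            iz = np.int64(np.floor(nz / L))
            nx -= ix * L
            ny -= iy * L
            nz -= iz * L
            if _overlap_at(p, nx, ny, nz, pos, L, edge, ncell, sigma2_lo,
                           chead, cnext, -1, parent, False):
                continue
            # an accepted move may not stretch any existing bond past range
            ok = True
            for k in range(deg[p]):
                q = adj[p, k]
                dx = _min_image_scalar(nx - pos[q, 0], L)
                dy = _min_image_scalar(ny - pos[q, 1], L)
                dz = _min_image_scalar(nz - pos[q, 2], L)
                if dx * dx + dy * dy + dz * dz > bond2_hi:
                    ok = False
                    break
            if not ok:
                continue
            pos[p, 0] = nx
            pos[p, 1] = ny
            pos[p, 2] = nz
            img[p, 0] += ix
            img[p, 1] += iy
            img[p, 2] += iz
            _cell_move(p, _cell_of(nx, ny, nz, edge, ncell),
                       chead, cnext, cprev, ccell)
            moved[p] = 1
            r = _find(parent, p)
            rouse[r, 0] += s * dirv[0]
            rouse[r, 1] += s * dirv[1]
            rouse[r, 2] += s * dirv[2]

        # ---- bond formation ------------------------------------------
        if bonding_enabled:
            status = _bond_pass(pos, img, species, deg, adj, parent, csize,
                                head_m, next_m, tail_m, span, rouse,
                                spec_span, gel_sweep, moved, chead, cnext,
                                L, edge, ncell, bond2_hi, sweep)
            if status != OK:
                return status

        # ---- Zimm cluster moves --------------------------------------
        if zimm_enabled:
            for r in range(n):
                if parent[r] != r or csize[r] < 2:
                    continue
                if span[r, 0] or span[r, 1] or span[r, 2]:
                    continue  # spanning clusters: diameter ~ box, D ~ 0
                # centre of mass and radius of gyration in the unwrapped frame
                cx = 0.0
                cy = 0.0
                cz = 0.0
                m = head_m[r]
                while m >= 0:
                    cx += pos[m, 0] + img[m, 0] * L
                    cy += pos[m, 1] + img[m, 1] * L
                    cz += pos[m, 2] + img[m, 2] * L
                    m = next_m[m]
                sz = csize[r]
                cx /= sz
                cy /= sz
                cz /= sz
                rg2 = 0.0
                m = head_m[r]
                while m >= 0:
                    dx = pos[m, 0] + img[m, 0] * L - cx
                    dy = pos[m, 1] + img[m, 1] * L - cy
                    dz = pos[m, 2] + img[m, 2] * L - cz
                    rg2 += dx * dx + dy * dy + dz * dz
                    m = next_m[m]
                rg2 /= sz
                d_c = 2.0 * np.sqrt(rg2) + sigma
                # direction: net Rouse displacement, or random if none
                rx = rouse[r, 0]
                ry = rouse[r, 1]
                rz = rouse[r, 2]
                rn = np.sqrt(rx * rx + ry * ry + rz * rz)
                if rn < 1e-14:
                    _rand_unit_vector(rng, dirv)
                    rx, ry, rz = dirv[0], dirv[1], dirv[2]
                else:
                    rx /= rn
                    ry /= rn
                    rz /= rn
                # magnitude: the kick is aligned with this sweep's Rouse COM
                # displacement R_com, so choosing (R_com + s_c)^2 equal to
                # s^2/m + s^2 sigma/d_c fixes the per-sweep COM MSD at the
                # ideal Rouse (D0/m; internal bond-rejections must not slow
                # the centre of mass) plus Zimm (D0 sigma/d_c) target.
                # Crowding still acts through wholesale rejection below.
                h2 = s * s / sz + s * s * sigma / d_c
                r_com = rn / sz
                s_c = np.sqrt(h2) - r_com
                if s_c <= 0.0:
                    continue
                dx = s_c * rx
                dy = s_c * ry
                dz = s_c * rz
                # trial: reject wholesale on any overlap with a non-member
                ok = True
                m = head_m[r]
                while m >= 0:
                    nx = pos[m, 0] + dx
                    ny = pos[m, 1] + dy
                    nz = pos[m, 2] + dz
                    nx -= np.floor(nx / L) * L
                    ny -= np.floor(ny / L) * L
                    nz -= np.floor(nz / L) * L
                    if _overlap_at(m, nx, ny, nz, pos, L, edge, ncell,
                                   sigma2_lo, chead, cnext, r, parent, True):
                        ok = False
                        break
                    m = next_m[m]
                if not ok:
                    continue
                m = head_m[r]
                while m >= 0:
                    nx = pos[m, 0] + dx
                    ny = pos[m, 1] + dy
                    nz = pos[m, 2] + dz
                    ix = np.int64(np.floor(nx / L))
                    iy = np.int64(np.floor(ny / L))
                    iz = np.int64(np.floor(nz / L))
                    pos[m, 0] = nx - ix * L
                    pos[m, 1] = ny - iy * L
                    pos[m, 2] = nz - iz * L
                    img[m, 0] += ix
                    img[m, 1] += iy
                    img[m, 2] += iz
                    _cell_move(m, _cell_of(pos[m, 0], pos[m, 1], pos[m, 2],
                                           edge, ncell),
                               chead, cnext, cprev, ccell)
                    moved[m] = 1
                    m = next_m[m]
    return OK


@njit(cache=True)
def initial_bond_pass(pos, img, species, deg, adj, parent, csize, head_m,
                      next_m, tail_m, span, rouse, spec_span, gel_sweep,
                      moved, chead, cnext, L, ncell, bond_range):
    """Bond pairs already within range in the initial configuration (t = 0)."""
    edge = L / ncell
    bond2_hi = bond_range * bond_range + 1e-12
    for i in range(pos.shape[0]):
        moved[i] = 1
    return _bond_pass(pos, img, species, deg, adj, parent, csize, head_m,
                      next_m, tail_m, span, rouse, spec_span, gel_sweep,
                      moved, chead, cnext, L, edge, ncell, bond2_hi, 0)


@njit(cache=True)
def rsa_pack(n, L, sigma, rng, max_tries_per_particle):
    """Random sequential insertion of n non-overlapping spheres.

    Returns (positions, ok_flag); insertion-order cell bookkeeping keeps
    the check O(1) per trial.  Practical up to phi ~ 0.35.
    """
    pos = np.empty((n, 3), dtype=np.float64)
    ncell = max(1, int(L / sigma))
    edge = L / ncell
    chead = np.full(ncell * ncell * ncell, -1, dtype=np.int64)
    cnext = np.full(n, -1, dtype=np.int64)
    sigma2 = sigma * sigma - 1e-12
    for i in range(n):
        placed = False
        for _ in range(max_tries_per_particle):
            x = _rng_uniform(rng) * L
            y = _rng_uniform(rng) * L
            z = _rng_uniform(rng) * L
            cx = int(x / edge)
            cy = int(y / edge)
            cz = int(z / edge)
            ok = True
            for ox in range(-1, 2):
                gx = (cx + ox) % ncell
                for oy in range(-1, 2):
                    gy = (cy + oy) % ncell
                    for oz in range(-1, 2):
                        gz = (cz + oz) % ncell
                        q = chead[(gx * ncell + gy) * ncell + gz]
                        while q >= 0:
                            dx = _min_image_scalar(x - pos[q, 0], L)
                            dy = _min_image_scalar(y - pos[q, 1], L)
                            dz = _min_image_scalar(z - pos[q, 2], L)
                            if dx * dx + dy * dy + dz * dz < sigma2:
                                ok = False
                                break
                            q = cnext[q]
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z
                c = _cell_of(x, y, z, edge, ncell)
                cnext[i] = chead[c]
                chead[c] = i
                placed = True
                break
        if not placed:
            return pos, False
    return pos, True


@njit(cache=True)
def roots_of(parent):
    """Root label of every particle (with path compression)."""
    n = parent.shape[0]
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        out[i] = _find(parent, i)
    return out
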