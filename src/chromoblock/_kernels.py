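"""Numba kernels: cell-list neighbor search, forces, energies, BAOAB loop.

Everything here works on plain float64/int64 arrays prepared by
``engine.py``.  Reduced units: m = 1, k_B = 1, so a thermostat temperature T
(in T0 units) means kT = T·ε0.

Status codes returned by ``integrate``:
0 = ok, 1 = FENE overstretch (r >= R0), 2 = non-finite coordinate,
3 = neighbor-pair capacity overflow (caller enlarges and reruns).
"""

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_FENE = 1
STATUS_NAN = 2
STATUS_OVERFLOW = 3


@njit(cache=True, fastmath=True)
def build_pairs(pos, cutoff, box_radius, types, eps_matrix,
                pair_i, pair_j, pair_eps):
    """Half neighbor list of all pairs within ``cutoff``.

    Counting-sort cell decomposition with contiguous per-cell coordinate
    slices (cache-friendly); fills the per-pair interaction strength from
    ``eps_matrix`` in the same pass.  Returns the number of pairs, or -1 on
    capacity overflow.
    """
    n = pos.shape[0]
    ncell = int(2.0 * box_radius / cutoff)
    cap_n = int(round((4.0 * n) ** (1.0 / 3.0))) + 1
    if ncell > cap_n:
        ncell = cap_n
    if ncell < 1:
        ncell = 1
    if ncell > 64:
        ncell = 64
    cell_size = 2.0 * box_radius / ncell
    nc2 = ncell * ncell
    nc3 = nc2 * ncell

    cell_of = np.empty(n, dtype=np.int64)
    start = np.zeros(nc3 + 1, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] + box_radius) / cell_size)
        cy = int((pos[i, 1] + box_radius) / cell_size)
        cz = int((pos[i, 2] + box_radius) / cell_size)
        if cx < 0:
            cx = 0
        elif cx >= ncell:
            cx = ncell - 1
        if cy < 0:
            cy = 0
        elif cy >= ncell:
            cy = ncell - 1
        if cz < 0:
            cz = 0
        elif cz >= ncell:
            cz = ncell - 1
        c = (cx * ncell + cy) * ncell + cz
        cell_of[i] = c
        start[c + 1] += 1
    for c in range(nc3):
        start[c + 1] += start[c]
    order = np.empty(n, dtype=np.int64)
    fill = np.empty(nc3, dtype=np.int64)
    for c in range(nc3):
        fill[c] = start[c]
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    sx = np.empty(n)
    sy = np.empty(n)
    sz = np.empty(n)
    st = np.empty(n, dtype=np.int64)
    for k in range(n):
        j = order[k]
        sx[k] = pos[j, 0]
        sy[k] = pos[j, 1]
        sz[k] = pos[j, 2]
        st[k] = types[j]

    cut2 = cutoff * cutoff
    cap = pair_i.shape[0]
    count = 0
    # half-space neighbor offsets (13) + the cell itself
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                a0 = start[c]
                a1 = start[c + 1]
                if a0 == a1:
                    continue
                # within the cell
                for k in range(a0, a1):
                    xk = sx[k]
                    yk = sy[k]
                    zk = sz[k]
                    for l in range(k + 1, a1):
                        dx = xk - sx[l]
                        dy = yk - sy[l]
                        dz = zk - sz[l]
                        if dx * dx + dy * dy + dz * dz < cut2:
                            if count >= cap:
                                return -1
                            pair_i[count] = order[k]
                            pair_j[count] = order[l]
                            pair_eps[count] = eps_matrix[st[k], st[l]]
                            count += 1
                # half of the 26 neighbour cells
                for o in range(13):
                    nx = cx + OFFSETS[o, 0]
                    ny = cy + OFFSETS[o, 1]
                    nz = cz + OFFSETS[o, 2]
                    if nx >= ncell or ny < 0 or ny >= ncell \
                            or nz < 0 or nz >= ncell:
                        continue
                    c2 = (nx * ncell + ny) * ncell + nz
                    b0 = start[c2]
                    b1 = start[c2 + 1]
                    for k in range(a0, a1):
                        xk = sx[k]
                        yk = sy[k]
                        zk = sz[k]
                        for l in range(b0, b1):
                            dx = xk - sx[l]
                            dy = yk - sy[l]
                            dz = zk - sz[l]
                            if dx * dx + dy * dy + dz * dz < cut2:
                                if count >= cap:
                                    return -1
                                pair_i[count] = order[k]
                                pair_j[count] = order[l]
                                pair_eps[count] = eps_matrix[st[k], st[l]]
                                count += 1
    return count


OFFSETS = np.array([
    [1, 0, 0], [1, 1, 0], [1, -1, 0], [0, 1, 0],
    [1, 0, 1], [1, 1, 1], [1, -1, 1], [0, 1, 1],
    [1, 0, -1], [1, 1, -1], [1, -1, -1], [0, 1, -1],
    [0, 0, 1],
], dtype=np.int64)


@njit(cache=True, fastmath=True)
def compute_forces(pos, forces, pair_eps, rc_pair,
                   bond_i, bond_j, fene_K, fene_R0,
                   bb_i, bb_j, bb_eps,
                   is_lad, R, eps_lc, rc_lad, eps_rep, rc_rep,
                   pair_i, pair_j, n_pairs):
    """Fill ``forces``; return STATUS_OK or STATUS_FENE."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0

    # FENE backbone
    R02 = fene_R0 * fene_R0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= R02:
            return STATUS_FENE
        g = -fene_K / (1.0 - r2 / R02)
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    # Harmonic TAD-boundary bonds: U = eps*r^2
    for b in range(bb_i.shape[0]):
        i = bb_i[b]
        j = bb_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        g = -2.0 * bb_eps[b]
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    # Truncated-shifted LJ on listed pairs
    rc2 = rc_pair * rc_pair
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2 and r2 > 1e-12:
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            g = 4.0 * pair_eps[p] * (12.0 * inv6 * inv6 - 6.0 * inv6) * inv2
            forces[i, 0] += g * dx
            forces[i, 1] += g * dy
            forces[i, 2] += g * dz
            forces[j, 0] -= g * dx
            forces[j, 1] -= g * dy
            forces[j, 2] -= g * dz

    # Spherical wall (cheap squared-distance precheck: the wall zone
    # starts 1.3 sigma from the surface at most)
    rin = R - 1.31
    if rin < 0.0:
        rin = 0.0
    rin2 = rin * rin
    for i in range(n):
        rho2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
        if rho2 < rin2:
            continue
        rho = math.sqrt(rho2)
        d = R - rho
        if d <= 0.0:
            return STATUS_FENE  # outside the container: reject
        if is_lad[i]:
            rc_w = rc_lad
            eps_w = eps_lc
        else:
            rc_w = rc_rep
            eps_w = eps_rep
        if d < rc_w and rho > 1e-10:
            invd2 = 1.0 / (d * d)
            invd6 = invd2 * invd2 * invd2
            # dU/dd = 4 eps (-12 d^-13 + 6 d^-7); F = U'(d) * rhat
            up = 4.0 * eps_w * (-12.0 * invd6 * invd6 + 6.0 * invd6) / d
            fx = up * pos[i, 0] / rho
            fy = up * pos[i, 1] / rho
            fz = up * pos[i, 2] / rho
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
    return STATUS_OK


@njit(cache=True)
def potential_energy(pos, types, eps_matrix, rc_pair,
                     bond_i, bond_j, fene_K, fene_R0,
                     bb_i, bb_j, bb_eps,
                     is_lad, R, eps_lc, rc_lad, eps_rep, rc_rep,
                     pair_i, pair_j, n_pairs):
    """Total potential over the same terms as compute_forces (inf on FENE
    overstretch or wall escape)."""
    e = 0.0
    R02 = fene_R0 * fene_R0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= R02:
            return np.inf
        e += -0.5 * fene_K * R02 * math.log(1.0 - r2 / R02)
    for b in range(bb_i.shape[0]):
        i = bb_i[b]
        j = bb_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        e += bb_eps[b] * (dx * dx + dy * dy + dz * dz)
    rc2 = rc_pair * rc_pair
    inv6c = (1.0 / rc_pair) ** 6
    shift = inv6c * inv6c - inv6c
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            eps = eps_matrix[types[i], types[j]]
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            e += 4.0 * eps * (inv6 * inv6 - inv6 - shift)
    for i in range(pos.shape[0]):
        rho = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        d = R - rho
        if d <= 0.0:
            return np.inf
        if is_lad[i]:
            rc_w = rc_lad
            eps_w = eps_lc
        else:
            rc_w = rc_rep
            eps_w = eps_rep
        if d < rc_w:
            invd6 = (1.0 / d) ** 6
            inv6cw = (1.0 / rc_w) ** 6
            e += 4.0 * eps_w * (invd6 * invd6 - invd6
                                - (inv6cw * inv6cw - inv6cw))
    return e


@njit(cache=True, fastmath=True)
def integrate_block(pos, vel, forces, pos_ref, pair_i, pair_j, pair_eps,
                    step0, nb, n_steps, dt, gamma, noise_stride,
                    t_start, t_end,
                    types, eps_matrix, rc_pair, skin,
                    bond_i, bond_j, fene_K, fene_R0,
                    bb_i, bb_j, bb_eps,
                    is_lad, R, eps_lc, rc_lad, eps_rep, rc_rep,
                    noise, snap_interval, frames, frame_steps,
                    log_pe, log_ke, log_temp, frame_count,
                    limit_steps, limit_dmax):
    """One block of ``nb`` Langevin steps (global steps step0..step0+nb).

    BAOAB splitting with the OU (thermostat) substep applied every
    ``noise_stride`` steps using the exact exp(-gamma*stride*dt) decay;
    gamma == 0 gives NVE velocity Verlet.  The thermostat target ramps
    linearly from t_start to t_end over the whole n_steps.  ``noise`` holds
    pre-drawn standard normals, 3n per applied OU substep.  The neighbor
    list is rebuilt on entry and whenever any bead moved more than half the
    skin.  For global steps below ``limit_steps`` the per-step displacement
    is capped at ``limit_dmax`` (gentle push-off from steep overlaps in
    fresh random conformations).
    Returns (status, failed_global_step, frame_count).
    """
    n = pos.shape[0]
    list_cut = rc_pair + skin
    n_pairs = build_pairs(pos, list_cut, R, types, eps_matrix,
                          pair_i, pair_j, pair_eps)
    if n_pairs < 0:
        return STATUS_OVERFLOW, step0, frame_count
    for i in range(n):
        pos_ref[i, 0] = pos[i, 0]
        pos_ref[i, 1] = pos[i, 1]
        pos_ref[i, 2] = pos[i, 2]
    st = compute_forces(pos, forces, pair_eps, rc_pair,
                        bond_i, bond_j, fene_K, fene_R0,
                        bb_i, bb_j, bb_eps,
                        is_lad, R, eps_lc, rc_lad, eps_rep, rc_rep,
                        pair_i, pair_j, n_pairs)
    if st != STATUS_OK:
        return st, step0, frame_count

    c1 = math.exp(-gamma * noise_stride * dt)
    denom = n_steps - 1 if n_steps > 1 else 1
    o_count = 0
    vmax = 0.0
    vmax2 = 0.0

    for k in range(nb):
        step = step0 + k
        capped = step < limit_steps
        if capped:
            # clip only collision spikes: 2.5x the instantaneous thermal
            # speed (tighter fixed cap during the initial push-off)
            temp_c = t_start + (t_end - t_start) * (step / denom)
            if temp_c < 0.05:
                temp_c = 0.05
            vmax = 2.0 * math.sqrt(3.0 * temp_c)
            if step < 10000 and vmax > limit_dmax / dt:
                vmax = limit_dmax / dt
            vmax2 = vmax * vmax

        # B (half kick) + optional velocity cap
        for i in range(n):
            vx = vel[i, 0] + 0.5 * dt * forces[i, 0]
            vy = vel[i, 1] + 0.5 * dt * forces[i, 1]
            vz = vel[i, 2] + 0.5 * dt * forces[i, 2]
            if capped:
                v2 = vx * vx + vy * vy + vz * vz
                if v2 > vmax2:
                    f = vmax / math.sqrt(v2)
                    vx *= f
                    vy *= f
                    vz *= f
            vel[i, 0] = vx
            vel[i, 1] = vy
            vel[i, 2] = vz

        # A - (O) - A fused with the neighbor-list displacement check
        apply_o = gamma > 0.0 and step % noise_stride == 0
        c2 = 0.0
        b0 = 0
        if apply_o:
            temp = t_start + (t_end - t_start) * (step / denom)
            if temp < 0.0:
                temp = 0.0
            c2 = math.sqrt((1.0 - c1 * c1) * temp)
            b0 = 3 * n * o_count
            o_count += 1
        take_snap = snap_interval > 0 and (step + 1) % snap_interval == 0
        ke_mid = 0.0
        max_d2 = 0.0
        max2_d2 = 0.0
        for i in range(n):
            vx = vel[i, 0]
            vy = vel[i, 1]
            vz = vel[i, 2]
            x = pos[i, 0] + 0.5 * dt * vx
            y = pos[i, 1] + 0.5 * dt * vy
            z = pos[i, 2] + 0.5 * dt * vz
            if apply_o:
                vx = c1 * vx + c2 * noise[b0 + 3 * i]
                vy = c1 * vy + c2 * noise[b0 + 3 * i + 1]
                vz = c1 * vz + c2 * noise[b0 + 3 * i + 2]
                if capped:
                    v2 = vx * vx + vy * vy + vz * vz
                    if v2 > vmax2:
                        f = vmax / math.sqrt(v2)
                        vx *= f
                        vy *= f
                        vz *= f
            if take_snap:
                ke_mid += vx * vx + vy * vy + vz * vz
            x += 0.5 * dt * vx
            y += 0.5 * dt * vy
            z += 0.5 * dt * vz
            vel[i, 0] = vx
            vel[i, 1] = vy
            vel[i, 2] = vz
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            dx = x - pos_ref[i, 0]
            dy = y - pos_ref[i, 1]
            dz = z - pos_ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > max_d2:
                max2_d2 = max_d2
                max_d2 = d2
            elif d2 > max2_d2:
                max2_d2 = d2

        # rebuild when the two most-displaced beads could jointly have
        # closed the skin gap
        if math.sqrt(max_d2) + math.sqrt(max2_d2) > skin:
            n_pairs = build_pairs(pos, list_cut, R, types, eps_matrix,
                                  pair_i, pair_j, pair_eps)
            if n_pairs < 0:
                return STATUS_OVERFLOW, step, frame_count
            for i in range(n):
                pos_ref[i, 0] = pos[i, 0]
                pos_ref[i, 1] = pos[i, 1]
                pos_ref[i, 2] = pos[i, 2]

        st = compute_forces(pos, forces, pair_eps, rc_pair,
                            bond_i, bond_j, fene_K, fene_R0,
                            bb_i, bb_j, bb_eps,
                            is_lad, R, eps_lc, rc_lad, eps_rep, rc_rep,
                            pair_i, pair_j, n_pairs)
        if st != STATUS_OK:
            return st, step, frame_count
        if not math.isfinite(pos[0, 0]):
            return STATUS_NAN, step, frame_count
        # B (half kick)
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]

        if take_snap:
            for i in range(n):
                frames[frame_count, i, 0] = pos[i, 0]
                frames[frame_count, i, 1] = pos[i, 1]
                frames[frame_count, i, 2] = pos[i, 2]
            frame_steps[frame_count] = step + 1
            ke = 0.0
            for i in range(n):
                ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            ke *= 0.5
            log_ke[frame_count] = ke
            # kinetic temperature from half-step (midpoint) velocities:
            # full-step velocities in velocity-Verlet-type schemes carry an
            # O((w*dt)^2) downward bias for stiff modes
            log_temp[frame_count] = ke_mid / (3.0 * n)
            log_pe[frame_count] = potential_energy(
                pos, types, eps_matrix, rc_pair,
                bond_i, bond_j, fene_K, fene_R0, bb_i, bb_j, bb_eps,
                is_lad, R, eps_lc, rc_lad, eps_rep, rc_rep,
                pair_i, pair_j, n_pairs)
            frame_count += 1
    return STATUS_OK, step0 + nb, frame_count


@njit(cache=True, fastmath=True)
def contact_counts(frames, threshold):
    """Sum over frames of the indicator d(i,j) < threshold; returns an n×n
    count matrix (upper+lower symmetric, diagonal zero)."""
    n_frames = frames.shape[0]
    n = frames.shape[1]
    counts = np.zeros((n, n), dtype=np.int64)
    t2 = threshold * threshold
    for f in range(n_frames):
        for i in range(n):
            xi = frames[f, i, 0]
            yi = frames[f, i, 1]
            zi = frames[f, i, 2]
            for j in range(i + 1, n):
                dx = xi - frames[f, j, 0]
                dy = yi - frames[f, j, 1]
                dz = zi - frames[f, j, 2]
                if dx * dx + dy * dy + dz * dz < t2:
                    counts[i, j] += 1
                    counts[j, i] += 1
    return counts
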