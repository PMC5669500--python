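"""Numba kernels for the dynamically triangulated membrane Monte Carlo engine.

All state lives in flat numpy arrays; the kernels maintain incremental
caches (triangle normals/areas/volume contributions, edge lengths and
dihedrals, per-vertex curvature and area, global scalars) so that a single
vertex move, edge flip or bead move costs O(vertex degree) instead of
O(mesh size).  A periodic full refresh removes floating-point drift and
re-anchors the bead -> closest-triangle assignments.

Scalar cache layout (``scal``):
    0: total area A           3: bending energy E_b (with kappa)
    1: enclosed volume V      4: adhesion energy E_bd
    2: sum of M_alpha         5: chain internal energy E_d

Parameter array layout (``pm``):
    0: kappa    4: A_ref    8: da_umb  12: d0
    1: K_A      5: V_ref    9: l_min   13: d1
    2: K_V      6: da_0    10: l_max   14: T
    3: K_da     7: k_umb   11: U       15: bead-bead min separation
"""

import numpy as np
from numba import njit

MAXD = 24          # hard cap on vertex degree
NCAND = 200        # candidate-triangle scratch size for bead searches

I_A, I_V, I_SM, I_EB, I_EBD, I_ED = 0, 1, 2, 3, 4, 5
(P_KAP, P_KA, P_KV, P_KDA, P_AREF, P_VREF, P_DA0, P_KUMB, P_DAUMB,
 P_LMIN, P_LMAX, P_U, P_D0, P_D1, P_T, P_SEP) = range(16)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _tri_geom(ax, ay, az, bx, by, bz, cx, cy, cz):
    """Unit normal, area, signed tetra-volume contribution of a triangle."""
    e1x, e1y, e1z = bx - ax, by - ay, bz - az
    e2x, e2y, e2z = cx - ax, cy - ay, cz - az
    nx = e1y * e2z - e1z * e2y
    ny = e1z * e2x - e1x * e2z
    nz = e1x * e2y - e1y * e2x
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    area = 0.5 * nn
    if nn < 1e-300:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    inv = 1.0 / nn
    vc = (ax * (by * cz - bz * cy)
          + ay * (bz * cx - bx * cz)
          + az * (bx * cy - by * cx)) / 6.0
    return nx * inv, ny * inv, nz * inv, area, vc


@njit(cache=True)
def _phi_val(n1x, n1y, n1z, n2x, n2y, n2z, ex, ey, ez):
    """Signed dihedral: atan2((n1 x n2).e, n1.n2); symmetric in the two
    triangles when e follows the first one's traversal."""
    cxx = n1y * n2z - n1z * n2y
    cyy = n1z * n2x - n1x * n2z
    czz = n1x * n2y - n1y * n2x
    s = cxx * ex + cyy * ey + czz * ez
    c = n1x * n2x + n1y * n2y + n1z * n2z
    return np.arctan2(s, c)


@njit(cache=True)
def _edge_dir_in_tri(tri, t, v0, v1):
    """+1 if (v0, v1) is a directed edge of triangle t, -1 if (v1, v0)."""
    for k in range(3):
        if tri[t, k] == v0 and tri[t, (k + 1) % 3] == v1:
            return 1.0
    return -1.0


@njit(cache=True)
def _pt_tri(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Squared distance and closest point from point p to triangle abc."""
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        qx, qy, qz = ax, ay, az
    else:
        bpx, bpy, bpz = px - bx, py - by, pz - bz
        d3 = abx * bpx + aby * bpy + abz * bpz
        d4 = acx * bpx + acy * bpy + acz * bpz
        if d3 >= 0.0 and d4 <= d3:
            qx, qy, qz = bx, by, bz
        else:
            vc = d1 * d4 - d3 * d2
            if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                t = d1 / (d1 - d3)
                qx, qy, qz = ax + t * abx, ay + t * aby, az + t * abz
            else:
                cpx, cpy, cpz = px - cx, py - cy, pz - cz
                d5 = abx * cpx + aby * cpy + abz * cpz
                d6 = acx * cpx + acy * cpy + acz * cpz
                if d6 >= 0.0 and d5 <= d6:
                    qx, qy, qz = cx, cy, cz
                else:
                    vb = d5 * d2 - d1 * d6
                    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                        w = d2 / (d2 - d6)
                        qx, qy, qz = ax + w * acx, ay + w * acy, az + w * acz
                    else:
                        va = d3 * d6 - d5 * d4
                        if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
                            w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                            qx = bx + w * (cx - bx)
                            qy = by + w * (cy - by)
                            qz = bz + w * (cz - bz)
                        else:
                            den = 1.0 / (va + vb + vc)
                            v = vb * den
                            w = vc * den
                            qx = ax + v * abx + w * acx
                            qy = ay + v * aby + w * acy
                            qz = az + v * abz + w * acz
    dx, dy, dz = px - qx, py - qy, pz - qz
    return dx * dx + dy * dy + dz * dz, qx, qy, qz


# ---------------------------------------------------------------------------
# full recompute of caches
# ---------------------------------------------------------------------------

@njit(cache=True)
def full_recompute(pos, tri, edge_v, edge_t, v_edges, v_deg,
                   tri_n, tri_a, tri_vc, e_len, e_phi, Mv, Av, scal, kappa):
    nt = tri.shape[0]
    ne = edge_v.shape[0]
    nv = pos.shape[0]
    A = 0.0
    V = 0.0
    for t in range(nt):
        i, j, k = tri[t, 0], tri[t, 1], tri[t, 2]
        nx, ny, nz, ar, vc = _tri_geom(
            pos[i, 0], pos[i, 1], pos[i, 2],
            pos[j, 0], pos[j, 1], pos[j, 2],
            pos[k, 0], pos[k, 1], pos[k, 2])
        tri_n[t, 0], tri_n[t, 1], tri_n[t, 2] = nx, ny, nz
        tri_a[t] = ar
        tri_vc[t] = vc
        A += ar
        V += vc
    for e in range(ne):
        v0, v1 = edge_v[e, 0], edge_v[e, 1]
        ex = pos[v1, 0] - pos[v0, 0]
        ey = pos[v1, 1] - pos[v0, 1]
        ez = pos[v1, 2] - pos[v0, 2]
        ln = np.sqrt(ex * ex + ey * ey + ez * ez)
        e_len[e] = ln
        d = _edge_dir_in_tri(tri, edge_t[e, 0], v0, v1) / ln
        t1, t2 = edge_t[e, 0], edge_t[e, 1]
        e_phi[e] = _phi_val(tri_n[t1, 0], tri_n[t1, 1], tri_n[t1, 2],
                            tri_n[t2, 0], tri_n[t2, 1], tri_n[t2, 2],
                            ex * d, ey * d, ez * d)
    sm = 0.0
    eb = 0.0
    for v in range(nv):
        m = 0.0
        av = 0.0
        for q in range(v_deg[v]):
            e = v_edges[v, q]
            m += e_len[e] * e_phi[e]
            av += tri_a[edge_t[e, 0]] + tri_a[edge_t[e, 1]]
        m *= 0.25
        av /= 6.0   # each incident triangle counted twice, vertex share 1/3
        Mv[v] = m
        Av[v] = av
        sm += m
        eb += 2.0 * kappa * m * m / av
    scal[I_A] = A
    scal[I_V] = V
    scal[I_SM] = sm
    scal[I_EB] = eb


@njit(cache=True)
def _cons_energy(A, V, sm, pm):
    e = 0.0
    if pm[P_KA] > 0.0:
        r = 1.0 - A / pm[P_AREF]
        e += pm[P_KA] * r * r
    if pm[P_KV] > 0.0:
        r = 1.0 - V / pm[P_VREF]
        e += pm[P_KV] * r * r
    if pm[P_KDA] > 0.0 or pm[P_KUMB] > 0.0:
        da = sm / (2.0 * np.sqrt(np.pi * A))
        if pm[P_KDA] > 0.0:
            r = 1.0 - da / pm[P_DA0]
            e += pm[P_KDA] * r * r
        if pm[P_KUMB] > 0.0:
            r = da - pm[P_DAUMB]
            e += 0.5 * pm[P_KUMB] * r * r
    return e


# ---------------------------------------------------------------------------
# bead helpers
# ---------------------------------------------------------------------------

@njit(cache=True)
def _bead_candidates(t0, tri, v_edges, v_deg, edge_t, cand):
    """Triangles sharing a vertex with triangle t0 (including t0)."""
    n = 0
    cand[n] = t0
    n += 1
    for q in range(3):
        w = tri[t0, q]
        for s in range(v_deg[w]):
            e = v_edges[w, s]
            for h in range(2):
                t = edge_t[e, h]
                seen = False
                for z in range(n):
                    if cand[z] == t:
                        seen = True
                        break
                if not seen and n < NCAND:
                    cand[n] = t
                    n += 1
    return n


@njit(cache=True)
def _tri_coords(t, tri, pos, iv, nxp, t1o, t2o, ov_tri):
    """Vertex coordinates of triangle t with optional overrides: vertex ``iv``
    is at ``nxp``; triangles ``t1o``/``t2o`` have the connectivity rows of
    ``ov_tri`` (trial flip)."""
    if t == t1o:
        i, j, k = ov_tri[0, 0], ov_tri[0, 1], ov_tri[0, 2]
    elif t == t2o:
        i, j, k = ov_tri[1, 0], ov_tri[1, 1], ov_tri[1, 2]
    else:
        i, j, k = tri[t, 0], tri[t, 1], tri[t, 2]
    out = np.empty((3, 3))
    idx = (i, j, k)
    for q in range(3):
        w = idx[q]
        if w == iv:
            out[q, 0], out[q, 1], out[q, 2] = nxp[0], nxp[1], nxp[2]
        else:
            out[q, 0], out[q, 1], out[q, 2] = pos[w, 0], pos[w, 1], pos[w, 2]
    return out


@njit(cache=True)
def _bead_closest(px, py, pz, cand, ncand, tri, pos, iv, nxp, t1o, t2o, ov_tri):
    """Closest triangle to a bead among candidates, with overrides.

    Returns (distance, triangle, side) where side = +-1 from the sign of
    (bead - foot) . outward normal of the closest triangle.
    """
    best = 1e300
    bt = -1
    bqx = bqy = bqz = 0.0
    for z in range(ncand):
        t = cand[z]
        co = _tri_coords(t, tri, pos, iv, nxp, t1o, t2o, ov_tri)
        d2, qx, qy, qz = _pt_tri(px, py, pz,
                                 co[0, 0], co[0, 1], co[0, 2],
                                 co[1, 0], co[1, 1], co[1, 2],
                                 co[2, 0], co[2, 1], co[2, 2])
        if d2 < best:
            best = d2
            bt = t
            bqx, bqy, bqz = qx, qy, qz
    co = _tri_coords(bt, tri, pos, iv, nxp, t1o, t2o, ov_tri)
    nx, ny, nz, _, _ = _tri_geom(co[0, 0], co[0, 1], co[0, 2],
                                 co[1, 0], co[1, 1], co[1, 2],
                                 co[2, 0], co[2, 1], co[2, 2])
    dp = (px - bqx) * nx + (py - bqy) * ny + (pz - bqz) * nz
    side = 1 if dp >= 0.0 else -1
    return np.sqrt(best), bt, side


@njit(cache=True)
def refresh_beads(bpos, tri, pos, tri_a, bead_tri, bead_dist, bead_side,
                  bead_eps, scal, pm):
    """Exact global closest-triangle assignment for every bead; resets E_bd."""
    nb = bpos.shape[0]
    nt = tri.shape[0]
    nxp = np.zeros(3)
    ov = np.zeros((2, 3), dtype=np.int64)
    ebd = 0.0
    for b in range(nb):
        best = 1e300
        bt = -1
        for t in range(nt):
            i, j, k = tri[t, 0], tri[t, 1], tri[t, 2]
            d2, _, _, _ = _pt_tri(bpos[b, 0], bpos[b, 1], bpos[b, 2],
                                  pos[i, 0], pos[i, 1], pos[i, 2],
                                  pos[j, 0], pos[j, 1], pos[j, 2],
                                  pos[k, 0], pos[k, 1], pos[k, 2])
            if d2 < best:
                best = d2
                bt = t
        cand = np.empty(1, dtype=np.int64)
        cand[0] = bt
        d, bt2, side = _bead_closest(bpos[b, 0], bpos[b, 1], bpos[b, 2],
                                     cand, 1, tri, pos, -1, nxp, -1, -1, ov)
        bead_tri[b] = bt
        bead_dist[b] = d
        bead_side[b] = side
        eps = 0.0
        if pm[P_D0] < d <= pm[P_D1]:
            eps = -pm[P_U] * tri_a[bt]
        bead_eps[b] = eps
        ebd += eps
    scal[I_EBD] = ebd


@njit(cache=True)
def chain_energy(bpos, c0, c1, bond_ref, th_ref, ga_ref, kb, ka, kd):
    """Harmonic internal energy of the chain occupying beads [c0, c1)."""
    n = c1 - c0
    e = 0.0
    for q in range(n - 1):
        dx = bpos[c0 + q + 1, 0] - bpos[c0 + q, 0]
        dy = bpos[c0 + q + 1, 1] - bpos[c0 + q, 1]
        dz = bpos[c0 + q + 1, 2] - bpos[c0 + q, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        dL = L - bond_ref[q]
        e += 0.5 * kb * dL * dL
    for q in range(n - 2):
        ax = bpos[c0 + q, 0] - bpos[c0 + q + 1, 0]
        ay = bpos[c0 + q, 1] - bpos[c0 + q + 1, 1]
        az = bpos[c0 + q, 2] - bpos[c0 + q + 1, 2]
        bx = bpos[c0 + q + 2, 0] - bpos[c0 + q + 1, 0]
        by = bpos[c0 + q + 2, 1] - bpos[c0 + q + 1, 1]
        bz = bpos[c0 + q + 2, 2] - bpos[c0 + q + 1, 2]
        na = np.sqrt(ax * ax + ay * ay + az * az)
        nb_ = np.sqrt(bx * bx + by * by + bz * bz)
        cth = (ax * bx + ay * by + az * bz) / (na * nb_)
        if cth > 1.0:
            cth = 1.0
        elif cth < -1.0:
            cth = -1.0
        dth = np.arccos(cth) - th_ref[q]
        e += 0.5 * ka * dth * dth
    if kd > 0.0:
        for q in range(n - 3):
            b1x = bpos[c0 + q + 1, 0] - bpos[c0 + q, 0]
            b1y = bpos[c0 + q + 1, 1] - bpos[c0 + q, 1]
            b1z = bpos[c0 + q + 1, 2] - bpos[c0 + q, 2]
            b2x = bpos[c0 + q + 2, 0] - bpos[c0 + q + 1, 0]
            b2y = bpos[c0 + q + 2, 1] - bpos[c0 + q + 1, 1]
            b2z = bpos[c0 + q + 2, 2] - bpos[c0 + q + 1, 2]
            b3x = bpos[c0 + q + 3, 0] - bpos[c0 + q + 2, 0]
            b3y = bpos[c0 + q + 3, 1] - bpos[c0 + q + 2, 1]
            b3z = bpos[c0 + q + 3, 2] - bpos[c0 + q + 2, 2]
            n1x = b1y * b2z - b1z * b2y
            n1y = b1z * b2x - b1x * b2z
            n1z = b1x * b2y - b1y * b2x
            n2x = b2y * b3z - b2z * b3y
            n2y = b2z * b3x - b2x * b3z
            n2z = b2x * b3y - b2y * b3x
            nn1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
            nn2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
            if nn1 < 1e-9 or nn2 < 1e-9:
                continue
            nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            m1x = n1y * b2z - n1z * b2y
            m1y = n1z * b2x - n1x * b2z
            m1z = n1x * b2y - n1y * b2x
            x = n1x * n2x + n1y * n2y + n1z * n2z
            y = (m1x * n2x + m1y * n2y + m1z * n2z) / nb2
            ga = np.arctan2(y, x)
            dg = ga - ga_ref[q]
            while dg > np.pi:
                dg -= 2.0 * np.pi
            while dg < -np.pi:
                dg += 2.0 * np.pi
            e += 0.5 * kd * dg * dg
    return e


# ---------------------------------------------------------------------------
# MC sweep driver
# ---------------------------------------------------------------------------

@njit(cache=True)
def _tether_ok(nl, ol, lmin, lmax):
    """Inside the interval, or (healing rule) strictly closer to it than the
    old length was — lets imperfect initial meshes relax into the bounds."""
    if lmin <= nl <= lmax:
        return True
    dn = lmin - nl if nl < lmin else nl - lmax
    do = 0.0
    if ol < lmin:
        do = lmin - ol
    elif ol > lmax:
        do = ol - lmax
    return dn < do


@njit(cache=True)
def run_phase(pos, tri, edge_v, edge_t, tri_edge, v_edges, v_deg,
              tri_n, tri_a, tri_vc, e_len, e_phi, Mv, Av, scal,
              bpos, chain_ptr, bond_ref, th_ref, ga_ref, kb_c, ka_c, kd_c,
              bead_tri, bead_dist, bead_side, bead_eps, ed_c,
              pm, n_sweeps,
              vref0, vref1, da00, da01, T0, T1,
              wv_in, wb_in, tune, width_follows_T,
              seed, refresh_stride, sample_stride, obs, flips_per_sweep):
    """Run ``n_sweeps`` Metropolis sweeps with linear ramps of V_ref, da_0
    and T.  One sweep = n_v vertex-move attempts + n_e flip attempts + one
    move attempt per bead.  Returns acceptance fractions and final widths.
    """
    np.random.seed(seed)
    nv = pos.shape[0]
    ne = edge_v.shape[0]
    nb = bpos.shape[0]
    nc = chain_ptr.shape[0] - 1
    kappa = pm[P_KAP]
    wv = wv_in
    wb = wb_in

    # scratch
    it_idx = np.empty(2 * MAXD, dtype=np.int64)
    new_tn = np.empty((2 * MAXD, 3))
    new_ta = np.empty(2 * MAXD)
    new_tvc = np.empty(2 * MAXD)
    ae_idx = np.empty(4 * MAXD, dtype=np.int64)
    new_el = np.empty(4 * MAXD)
    new_ephi = np.empty(4 * MAXD)
    av_idx = np.empty(MAXD + 1, dtype=np.int64)
    new_M = np.empty(MAXD + 1)
    new_Av = np.empty(MAXD + 1)
    cand = np.empty(NCAND, dtype=np.int64)
    nxp = np.zeros(3)
    ov_tri = np.zeros((2, 3), dtype=np.int64)
    aff_b = np.empty(max(nb, 1), dtype=np.int64)
    nb_tri = np.empty(max(nb, 1), dtype=np.int64)
    nb_dist = np.empty(max(nb, 1))
    nb_side = np.empty(max(nb, 1), dtype=np.int64)
    nb_eps = np.empty(max(nb, 1))

    acc = np.zeros(6)  # acc_v, att_v, acc_f, att_f, acc_b, att_b
    win = np.zeros(4)  # tuning window counters (vertex acc/att, bead acc/att)
    n_obs_col = 9
    obs_row = 0

    for sweep in range(n_sweeps):
        frac = (sweep + 1.0) / n_sweeps
        pm[P_VREF] = vref0 + (vref1 - vref0) * frac
        pm[P_DA0] = da00 + (da01 - da00) * frac
        T = T0 + (T1 - T0) * frac
        pm[P_T] = T
        wv_eff = wv
        wb_eff = wb
        if width_follows_T == 1 and T0 > 0.0:
            sc = np.sqrt(T / T0)
            if sc < 0.05:
                sc = 0.05
            wv_eff = wv * sc
            wb_eff = wb * sc

        if refresh_stride > 0 and sweep % refresh_stride == 0:
            full_recompute(pos, tri, edge_v, edge_t, v_edges, v_deg,
                           tri_n, tri_a, tri_vc, e_len, e_phi, Mv, Av,
                           scal, kappa)
            if nb > 0:
                refresh_beads(bpos, tri, pos, tri_a, bead_tri, bead_dist,
                              bead_side, bead_eps, scal, pm)
                edtot = 0.0
                for c in range(nc):
                    ed_c[c] = chain_energy(bpos, chain_ptr[c], chain_ptr[c + 1],
                                           bond_ref[c], th_ref[c], ga_ref[c],
                                           kb_c[c], ka_c[c], kd_c[c])
                    edtot += ed_c[c]
                scal[I_ED] = edtot

        # ------------------------------------------------------ vertex moves
        for _ in range(nv):
            iv = int(np.random.random() * nv)
            if iv >= nv:
                iv = nv - 1
            nxp[0] = pos[iv, 0] + wv_eff * (np.random.random() - 0.5) * 2.0
            nxp[1] = pos[iv, 1] + wv_eff * (np.random.random() - 0.5) * 2.0
            nxp[2] = pos[iv, 2] + wv_eff * (np.random.random() - 0.5) * 2.0
            acc[1] += 1.0
            win[1] += 1.0
            deg = v_deg[iv]

            # tether on spokes
            ok = True
            for q in range(deg):
                e = v_edges[iv, q]
                other = edge_v[e, 0] + edge_v[e, 1] - iv
                dx = nxp[0] - pos[other, 0]
                dy = nxp[1] - pos[other, 1]
                dz = nxp[2] - pos[other, 2]
                nl = np.sqrt(dx * dx + dy * dy + dz * dz)
                if not _tether_ok(nl, e_len[e], pm[P_LMIN], pm[P_LMAX]):
                    ok = False
                    break
            if not ok:
                continue

            # incident triangles (dedup over spoke edge_t pairs)
            nit = 0
            for q in range(deg):
                e = v_edges[iv, q]
                for h in range(2):
                    t = edge_t[e, h]
                    seen = False
                    for z in range(nit):
                        if it_idx[z] == t:
                            seen = True
                            break
                    if not seen:
                        it_idx[nit] = t
                        nit += 1
            # new geometry of incident triangles
            degen = False
            for z in range(nit):
                t = it_idx[z]
                co = _tri_coords(t, tri, pos, iv, nxp, -1, -1, ov_tri)
                nx, ny, nz, ar, vc = _tri_geom(co[0, 0], co[0, 1], co[0, 2],
                                               co[1, 0], co[1, 1], co[1, 2],
                                               co[2, 0], co[2, 1], co[2, 2])
                if ar < 1e-9:
                    degen = True
                    break
                new_tn[z, 0], new_tn[z, 1], new_tn[z, 2] = nx, ny, nz
                new_ta[z] = ar
                new_tvc[z] = vc
            if degen:
                continue

            # affected edges = edges of incident triangles
            nae = 0
            for z in range(nit):
                t = it_idx[z]
                for h in range(3):
                    e = tri_edge[t, h]
                    seen = False
                    for y in range(nae):
                        if ae_idx[y] == e:
                            seen = True
                            break
                    if not seen:
                        ae_idx[nae] = e
                        nae += 1
            # new lengths and dihedrals of affected edges
            for y in range(nae):
                e = ae_idx[y]
                v0, v1 = edge_v[e, 0], edge_v[e, 1]
                x0, y0_, z0 = pos[v0, 0], pos[v0, 1], pos[v0, 2]
                if v0 == iv:
                    x0, y0_, z0 = nxp[0], nxp[1], nxp[2]
                x1, y1_, z1 = pos[v1, 0], pos[v1, 1], pos[v1, 2]
                if v1 == iv:
                    x1, y1_, z1 = nxp[0], nxp[1], nxp[2]
                ex, ey, ez = x1 - x0, y1_ - y0_, z1 - z0
                ln = np.sqrt(ex * ex + ey * ey + ez * ez)
                new_el[y] = ln
                t1, t2 = edge_t[e, 0], edge_t[e, 1]
                # normals with overrides
                n1x, n1y, n1z = tri_n[t1, 0], tri_n[t1, 1], tri_n[t1, 2]
                n2x, n2y, n2z = tri_n[t2, 0], tri_n[t2, 1], tri_n[t2, 2]
                for z in range(nit):
                    if it_idx[z] == t1:
                        n1x, n1y, n1z = new_tn[z, 0], new_tn[z, 1], new_tn[z, 2]
                    if it_idx[z] == t2:
                        n2x, n2y, n2z = new_tn[z, 0], new_tn[z, 1], new_tn[z, 2]
                d = _edge_dir_in_tri(tri, t1, v0, v1) / ln
                new_ephi[y] = _phi_val(n1x, n1y, n1z, n2x, n2y, n2z,
                                       ex * d, ey * d, ez * d)

            # affected vertices: iv + spoke partners
            nav = 0
            av_idx[nav] = iv
            nav += 1
            for q in range(deg):
                e = v_edges[iv, q]
                av_idx[nav] = edge_v[e, 0] + edge_v[e, 1] - iv
                nav += 1
            dEb = 0.0
            dsm = 0.0
            for z in range(nav):
                vv = av_idx[z]
                m = 0.0
                av2 = 0.0
                for q in range(v_deg[vv]):
                    e = v_edges[vv, q]
                    le = e_len[e]
                    ph = e_phi[e]
                    for y in range(nae):
                        if ae_idx[y] == e:
                            le = new_el[y]
                            ph = new_ephi[y]
                            break
                    m += le * ph
                    t1, t2 = edge_t[e, 0], edge_t[e, 1]
                    a1 = tri_a[t1]
                    a2 = tri_a[t2]
                    for w in range(nit):
                        if it_idx[w] == t1:
                            a1 = new_ta[w]
                        if it_idx[w] == t2:
                            a2 = new_ta[w]
                    av2 += a1 + a2
                m *= 0.25
                av2 /= 6.0
                new_M[z] = m
                new_Av[z] = av2
                dEb += 2.0 * kappa * (m * m / av2 - Mv[vv] * Mv[vv] / Av[vv])
                dsm += m - Mv[vv]
            dA = 0.0
            dV = 0.0
            for z in range(nit):
                t = it_idx[z]
                dA += new_ta[z] - tri_a[t]
                dV += new_tvc[z] - tri_vc[t]

            # beads near the move
            dEbd = 0.0
            naff = 0
            rej = False
            if nb > 0:
                cut = pm[P_D1] + pm[P_LMAX] + wv_eff
                cut2 = cut * cut
                for b in range(nb):
                    hit = False
                    bt = bead_tri[b]
                    for z in range(nit):
                        if it_idx[z] == bt:
                            hit = True
                            break
                    if not hit:
                        dx = bpos[b, 0] - pos[iv, 0]
                        dy = bpos[b, 1] - pos[iv, 1]
                        dz = bpos[b, 2] - pos[iv, 2]
                        if dx * dx + dy * dy + dz * dz < cut2:
                            hit = True
                    if not hit:
                        continue
                    ncd = _bead_candidates(bt, tri, v_edges, v_deg, edge_t, cand)
                    for z in range(nit):
                        t = it_idx[z]
                        seen = False
                        for y in range(ncd):
                            if cand[y] == t:
                                seen = True
                                break
                        if not seen and ncd < NCAND:
                            cand[ncd] = t
                            ncd += 1
                    d, bt2, side = _bead_closest(
                        bpos[b, 0], bpos[b, 1], bpos[b, 2],
                        cand, ncd, tri, pos, iv, nxp, -1, -1, ov_tri)
                    if d <= pm[P_D0] or side != bead_side[b]:
                        rej = True
                        break
                    eps = 0.0
                    if d <= pm[P_D1]:
                        a2 = tri_a[bt2]
                        for z in range(nit):
                            if it_idx[z] == bt2:
                                a2 = new_ta[z]
                        eps = -pm[P_U] * a2
                    aff_b[naff] = b
                    nb_tri[naff] = bt2
                    nb_dist[naff] = d
                    nb_side[naff] = side
                    nb_eps[naff] = eps
                    dEbd += eps - bead_eps[b]
                    naff += 1
            if rej:
                continue

            dC = (_cons_energy(scal[I_A] + dA, scal[I_V] + dV,
                               scal[I_SM] + dsm, pm)
                  - _cons_energy(scal[I_A], scal[I_V], scal[I_SM], pm))
            dE = dEb + dC + dEbd
            if dE > 0.0:
                if T < 1e-12 or np.random.random() >= np.exp(-dE / T):
                    continue
            # commit
            pos[iv, 0], pos[iv, 1], pos[iv, 2] = nxp[0], nxp[1], nxp[2]
            for z in range(nit):
                t = it_idx[z]
                tri_n[t, 0], tri_n[t, 1], tri_n[t, 2] = (
                    new_tn[z, 0], new_tn[z, 1], new_tn[z, 2])
                tri_a[t] = new_ta[z]
                tri_vc[t] = new_tvc[z]
            for y in range(nae):
                e = ae_idx[y]
                e_len[e] = new_el[y]
                e_phi[e] = new_ephi[y]
            for z in range(nav):
                vv = av_idx[z]
                Mv[vv] = new_M[z]
                Av[vv] = new_Av[z]
            scal[I_A] += dA
            scal[I_V] += dV
            scal[I_SM] += dsm
            scal[I_EB] += dEb
            scal[I_EBD] += dEbd
            for z in range(naff):
                b = aff_b[z]
                bead_tri[b] = nb_tri[z]
                bead_dist[b] = nb_dist[z]
                bead_side[b] = nb_side[z]
                bead_eps[b] = nb_eps[z]
            acc[0] += 1.0
            win[0] += 1.0

        # ------------------------------------------------------- edge flips
        for _ in range(flips_per_sweep):
            e = int(np.random.random() * ne)
            if e >= ne:
                e = ne - 1
            acc[3] += 1.0
            a, b_ = edge_v[e, 0], edge_v[e, 1]
            t1, t2 = edge_t[e, 0], edge_t[e, 1]
            # orient a -> b as traversed in t1
            if _edge_dir_in_tri(tri, t1, a, b_) < 0.0:
                a, b_ = b_, a
            c = -1
            d_ = -1
            for q in range(3):
                w = tri[t1, q]
                if w != a and w != b_:
                    c = w
                w = tri[t2, q]
                if w != a and w != b_:
                    d_ = w
            if c == d_ or c < 0 or d_ < 0:
                continue
            if v_deg[a] <= 3 or v_deg[b_] <= 3:
                continue
            if v_deg[c] >= MAXD or v_deg[d_] >= MAXD:
                continue
            # opposite diagonal must not exist
            exists = False
            for q in range(v_deg[c]):
                ee = v_edges[c, q]
                if edge_v[ee, 0] + edge_v[ee, 1] - c == d_:
                    exists = True
                    break
            if exists:
                continue
            dx = pos[c, 0] - pos[d_, 0]
            dy = pos[c, 1] - pos[d_, 1]
            dz = pos[c, 2] - pos[d_, 2]
            nl = np.sqrt(dx * dx + dy * dy + dz * dz)
            if nl < pm[P_LMIN] or nl > pm[P_LMAX]:
                continue
            # new triangles (c,a,d) and (d,b,c)
            n1x, n1y, n1z, a1n, v1n = _tri_geom(
                pos[c, 0], pos[c, 1], pos[c, 2],
                pos[a, 0], pos[a, 1], pos[a, 2],
                pos[d_, 0], pos[d_, 1], pos[d_, 2])
            n2x, n2y, n2z, a2n, v2n = _tri_geom(
                pos[d_, 0], pos[d_, 1], pos[d_, 2],
                pos[b_, 0], pos[b_, 1], pos[b_, 2],
                pos[c, 0], pos[c, 1], pos[c, 2])
            if a1n < 1e-9 or a2n < 1e-9:
                continue
            sx = tri_n[t1, 0] + tri_n[t2, 0]
            sy = tri_n[t1, 1] + tri_n[t2, 1]
            sz = tri_n[t1, 2] + tri_n[t2, 2]
            if (n1x * sx + n1y * sy + n1z * sz) <= 0.0 or \
               (n2x * sx + n2y * sy + n2z * sz) <= 0.0:
                continue  # non-convex quadrilateral: orientation would invert

            # locate boundary edges ac, ad, bc, bd
            e_ac = e_ad = e_bc = e_bd = -1
            for q in range(v_deg[a]):
                ee = v_edges[a, q]
                o = edge_v[ee, 0] + edge_v[ee, 1] - a
                if o == c:
                    e_ac = ee
                elif o == d_:
                    e_ad = ee
            for q in range(v_deg[b_]):
                ee = v_edges[b_, q]
                o = edge_v[ee, 0] + edge_v[ee, 1] - b_
                if o == c:
                    e_bc = ee
                elif o == d_:
                    e_bd = ee
            # new dihedral of the flipped edge: traversed (d,c) in (c,a,d)
            inl = 1.0 / nl
            phi_e = _phi_val(n1x, n1y, n1z, n2x, n2y, n2z,
                             dx * inl, dy * inl, dz * inl)
            # boundary edges: new inside normal + outer stored normal
            # (phi is symmetric in the two triangles, so traversal may follow
            # the new inside triangle)
            # ac -> inside (c,a,d) traverses (c,a)
            phi_b = np.empty(4)
            be = (e_ac, e_ad, e_bd, e_bc)
            # traversal vectors for (c,a) in T1, (a,d) in T1, (d,b) in T2, (b,c) in T2
            tvx = (pos[a, 0] - pos[c, 0], pos[d_, 0] - pos[a, 0],
                   pos[b_, 0] - pos[d_, 0], pos[c, 0] - pos[b_, 0])
            tvy = (pos[a, 1] - pos[c, 1], pos[d_, 1] - pos[a, 1],
                   pos[b_, 1] - pos[d_, 1], pos[c, 1] - pos[b_, 1])
            tvz = (pos[a, 2] - pos[c, 2], pos[d_, 2] - pos[a, 2],
                   pos[b_, 2] - pos[d_, 2], pos[c, 2] - pos[b_, 2])
            ins_n = ((n1x, n1y, n1z), (n1x, n1y, n1z),
                     (n2x, n2y, n2z), (n2x, n2y, n2z))
            old_in = (t1, t2, t2, t1)
            okf = True
            for q in range(4):
                ee = be[q]
                if ee < 0:
                    okf = False
                    break
                t_out = edge_t[ee, 0]
                if t_out == old_in[q]:
                    t_out = edge_t[ee, 1]
                ln2 = np.sqrt(tvx[q] * tvx[q] + tvy[q] * tvy[q] + tvz[q] * tvz[q])
                phi_b[q] = _phi_val(ins_n[q][0], ins_n[q][1], ins_n[q][2],
                                    tri_n[t_out, 0], tri_n[t_out, 1],
                                    tri_n[t_out, 2],
                                    tvx[q] / ln2, tvy[q] / ln2, tvz[q] / ln2)
            if not okf:
                continue

            # M updates
            q_ac = 0.25 * e_len[e_ac] * (phi_b[0] - e_phi[e_ac])
            q_ad = 0.25 * e_len[e_ad] * (phi_b[1] - e_phi[e_ad])
            q_bd = 0.25 * e_len[e_bd] * (phi_b[2] - e_phi[e_bd])
            q_bc = 0.25 * e_len[e_bc] * (phi_b[3] - e_phi[e_bc])
            q_e_old = 0.25 * e_len[e] * e_phi[e]
            q_e_new = 0.25 * nl * phi_e
            Ma = Mv[a] + q_ac + q_ad - q_e_old
            Mb = Mv[b_] + q_bc + q_bd - q_e_old
            Mc = Mv[c] + q_ac + q_bc + q_e_new
            Md = Mv[d_] + q_ad + q_bd + q_e_new
            a1o = tri_a[t1]
            a2o = tri_a[t2]
            Ava = Av[a] + (a1n - a1o - a2o) / 3.0
            Avb = Av[b_] + (a2n - a1o - a2o) / 3.0
            Avc = Av[c] + (a1n + a2n - a1o) / 3.0
            Avd = Av[d_] + (a1n + a2n - a2o) / 3.0
            if Ava <= 0.0 or Avb <= 0.0 or Avc <= 0.0 or Avd <= 0.0:
                continue
            dEb = 2.0 * kappa * (
                Ma * Ma / Ava - Mv[a] * Mv[a] / Av[a]
                + Mb * Mb / Avb - Mv[b_] * Mv[b_] / Av[b_]
                + Mc * Mc / Avc - Mv[c] * Mv[c] / Av[c]
                + Md * Md / Avd - Mv[d_] * Mv[d_] / Av[d_])
            dsm = (Ma - Mv[a]) + (Mb - Mv[b_]) + (Mc - Mv[c]) + (Md - Mv[d_])
            dA = a1n + a2n - a1o - a2o
            dV = v1n + v2n - tri_vc[t1] - tri_vc[t2]

            # beads on the flipped triangles or near the quad
            dEbd = 0.0
            naff = 0
            rej = False
            if nb > 0:
                ov_tri[0, 0], ov_tri[0, 1], ov_tri[0, 2] = c, a, d_
                ov_tri[1, 0], ov_tri[1, 1], ov_tri[1, 2] = d_, b_, c
                cut = pm[P_D1] + pm[P_LMAX]
                cut2 = cut * cut
                for bb in range(nb):
                    bt = bead_tri[bb]
                    hit = bt == t1 or bt == t2
                    if not hit:
                        ddx = bpos[bb, 0] - pos[c, 0]
                        ddy = bpos[bb, 1] - pos[c, 1]
                        ddz = bpos[bb, 2] - pos[c, 2]
                        if ddx * ddx + ddy * ddy + ddz * ddz < cut2:
                            hit = True
                        else:
                            ddx = bpos[bb, 0] - pos[d_, 0]
                            ddy = bpos[bb, 1] - pos[d_, 1]
                            ddz = bpos[bb, 2] - pos[d_, 2]
                            if ddx * ddx + ddy * ddy + ddz * ddz < cut2:
                                hit = True
                    if not hit:
                        continue
                    ncd = _bead_candidates(bt, tri, v_edges, v_deg, edge_t, cand)
                    for tt in (t1, t2):
                        seen = False
                        for y in range(ncd):
                            if cand[y] == tt:
                                seen = True
                                break
                        if not seen and ncd < NCAND:
                            cand[ncd] = tt
                            ncd += 1
                    d, bt2, side = _bead_closest(
                        bpos[bb, 0], bpos[bb, 1], bpos[bb, 2],
                        cand, ncd, tri, pos, -1, nxp, t1, t2, ov_tri)
                    if d <= pm[P_D0] or side != bead_side[bb]:
                        rej = True
                        break
                    eps = 0.0
                    if d <= pm[P_D1]:
                        at = tri_a[bt2]
                        if bt2 == t1:
                            at = a1n
                        elif bt2 == t2:
                            at = a2n
                        eps = -pm[P_U] * at
                    aff_b[naff] = bb
                    nb_tri[naff] = bt2
                    nb_dist[naff] = d
                    nb_side[naff] = side
                    nb_eps[naff] = eps
                    dEbd += eps - bead_eps[bb]
                    naff += 1
            if rej:
                continue

            dC = (_cons_energy(scal[I_A] + dA, scal[I_V] + dV,
                               scal[I_SM] + dsm, pm)
                  - _cons_energy(scal[I_A], scal[I_V], scal[I_SM], pm))
            dE = dEb + dC + dEbd
            T = pm[P_T]
            if dE > 0.0:
                if T < 1e-12 or np.random.random() >= np.exp(-dE / T):
                    continue

            # ---- commit structural update
            tri[t1, 0], tri[t1, 1], tri[t1, 2] = c, a, d_
            tri[t2, 0], tri[t2, 1], tri[t2, 2] = d_, b_, c
            edge_v[e, 0], edge_v[e, 1] = d_, c
            edge_t[e, 0], edge_t[e, 1] = t1, t2
            tri_edge[t1, 0], tri_edge[t1, 1], tri_edge[t1, 2] = e_ac, e_ad, e
            tri_edge[t2, 0], tri_edge[t2, 1], tri_edge[t2, 2] = e_bd, e_bc, e
            if edge_t[e_ad, 0] == t2:
                edge_t[e_ad, 0] = t1
            elif edge_t[e_ad, 1] == t2:
                edge_t[e_ad, 1] = t1
            if edge_t[e_bc, 0] == t1:
                edge_t[e_bc, 0] = t2
            elif edge_t[e_bc, 1] == t1:
                edge_t[e_bc, 1] = t2
            # v_edges: remove e from a and b_, add to c and d_
            for vv in (a, b_):
                for q in range(v_deg[vv]):
                    if v_edges[vv, q] == e:
                        v_edges[vv, q] = v_edges[vv, v_deg[vv] - 1]
                        v_deg[vv] -= 1
                        break
            v_edges[c, v_deg[c]] = e
            v_deg[c] += 1
            v_edges[d_, v_deg[d_]] = e
            v_deg[d_] += 1
            # caches
            tri_n[t1, 0], tri_n[t1, 1], tri_n[t1, 2] = n1x, n1y, n1z
            tri_n[t2, 0], tri_n[t2, 1], tri_n[t2, 2] = n2x, n2y, n2z
            tri_a[t1] = a1n
            tri_a[t2] = a2n
            tri_vc[t1] = v1n
            tri_vc[t2] = v2n
            e_len[e] = nl
            e_phi[e] = phi_e
            e_phi[e_ac] = phi_b[0]
            e_phi[e_ad] = phi_b[1]
            e_phi[e_bd] = phi_b[2]
            e_phi[e_bc] = phi_b[3]
            Mv[a], Mv[b_], Mv[c], Mv[d_] = Ma, Mb, Mc, Md
            Av[a], Av[b_], Av[c], Av[d_] = Ava, Avb, Avc, Avd
            scal[I_A] += dA
            scal[I_V] += dV
            scal[I_SM] += dsm
            scal[I_EB] += dEb
            scal[I_EBD] += dEbd
            for z in range(naff):
                bb = aff_b[z]
                bead_tri[bb] = nb_tri[z]
                bead_dist[bb] = nb_dist[z]
                bead_side[bb] = nb_side[z]
                bead_eps[bb] = nb_eps[z]
            acc[2] += 1.0

        # ------------------------------------------------------- bead moves
        for _ in range(nb):
            b = int(np.random.random() * nb)
            if b >= nb:
                b = nb - 1
            acc[5] += 1.0
            win[3] += 1.0
            npx = bpos[b, 0] + wb_eff * (np.random.random() - 0.5) * 2.0
            npy = bpos[b, 1] + wb_eff * (np.random.random() - 0.5) * 2.0
            npz = bpos[b, 2] + wb_eff * (np.random.random() - 0.5) * 2.0
            # chain of b
            ci = 0
            for c_ in range(nc):
                if chain_ptr[c_] <= b < chain_ptr[c_ + 1]:
                    ci = c_
                    break
            # inter-dimer excluded volume
            sep2 = pm[P_SEP] * pm[P_SEP]
            clash = False
            for b2 in range(nb):
                if chain_ptr[ci] <= b2 < chain_ptr[ci + 1]:
                    continue
                ddx = npx - bpos[b2, 0]
                ddy = npy - bpos[b2, 1]
                ddz = npz - bpos[b2, 2]
                if ddx * ddx + ddy * ddy + ddz * ddz < sep2:
                    clash = True
                    break
            if clash:
                continue
            ncd = _bead_candidates(bead_tri[b], tri, v_edges, v_deg, edge_t, cand)
            d, bt2, side = _bead_closest(npx, npy, npz, cand, ncd,
                                         tri, pos, -1, nxp, -1, -1, ov_tri)
            if d <= pm[P_D0] or side != bead_side[b]:
                continue
            eps = 0.0
            if d <= pm[P_D1]:
                eps = -pm[P_U] * tri_a[bt2]
            dEbd = eps - bead_eps[b]
            ox, oy, oz = bpos[b, 0], bpos[b, 1], bpos[b, 2]
            bpos[b, 0], bpos[b, 1], bpos[b, 2] = npx, npy, npz
            ed_new = chain_energy(bpos, chain_ptr[ci], chain_ptr[ci + 1],
                                  bond_ref[ci], th_ref[ci], ga_ref[ci],
                                  kb_c[ci], ka_c[ci], kd_c[ci])
            dEd = ed_new - ed_c[ci]
            dE = dEbd + dEd
            T = pm[P_T]
            if dE > 0.0 and (T < 1e-12 or np.random.random() >= np.exp(-dE / T)):
                bpos[b, 0], bpos[b, 1], bpos[b, 2] = ox, oy, oz
                continue
            bead_tri[b] = bt2
            bead_dist[b] = d
            bead_side[b] = side
            bead_eps[b] = eps
            ed_c[ci] = ed_new
            scal[I_EBD] += dEbd
            scal[I_ED] += dEd
            acc[4] += 1.0
            win[2] += 1.0

        # -------------------------------------------------------- tuning
        if tune == 1 and (sweep + 1) % 50 == 0:
            if win[1] > 0:
                r = win[0] / win[1]
                if r > 0.45:
                    wv *= 1.2
                elif r < 0.35:
                    wv *= 0.85
            if win[3] > 0:
                r = win[2] / win[3]
                if r > 0.45:
                    wb *= 1.2
                elif r < 0.35:
                    wb *= 0.85
            win[:] = 0.0

        # -------------------------------------------------------- sampling
        if sample_stride > 0 and (sweep + 1) % sample_stride == 0 \
                and obs_row < obs.shape[0]:
            A = scal[I_A]
            obs[obs_row, 0] = sweep + 1.0
            obs[obs_row, 1] = scal[I_EB]
            obs[obs_row, 2] = A
            obs[obs_row, 3] = scal[I_V]
            obs[obs_row, 4] = 6.0 * np.sqrt(np.pi) * scal[I_V] / A ** 1.5
            obs[obs_row, 5] = scal[I_SM] / (2.0 * np.sqrt(np.pi * A))
            obs[obs_row, 6] = scal[I_EBD]
            obs[obs_row, 7] = scal[I_ED]
            obs[obs_row, 8] = T
            obs_row += 1

    return acc, wv, wb, obs_row
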