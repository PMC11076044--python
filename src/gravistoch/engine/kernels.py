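"""Numba kernels for box rigid-body dynamics.

Everything here operates on flat numpy arrays so the hot loop (contact
generation + sequential-impulse solving, once per integration step) stays
free of Python overhead.  Conventions:

* quaternions are (w, x, y, z), unit norm;
* a contact is the tuple (a, b, point, normal, separation) where ``b == -1``
  denotes the static ground plane z=0, the normal points from b toward a and
  ``separation < 0`` means penetration;
* bodies with ``invm == 0`` are immovable (ground stand-ins or sleeping
  bodies pinned for the current step).
"""

import numpy as np
from numba import njit

# sign pattern of the 8 box vertices, lexicographic in (x, y, z)
_SIGNS = np.array(
    [
        [-1.0, -1.0, -1.0],
        [-1.0, -1.0, 1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [1.0, -1.0, 1.0],
        [1.0, 1.0, -1.0],
        [1.0, 1.0, 1.0],
    ]
)

MAX_CONTACTS = 4096


@njit(cache=True)
def quat_to_mat(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)


@njit(cache=True)
def all_rotations(quat, R):
    for i in range(quat.shape[0]):
        quat_to_mat(quat[i], R[i])


@njit(cache=True)
def box_vertices(pos, R, half, signs, out):
    """World vertices of every body: out[i, v, :]."""
    n = pos.shape[0]
    for i in range(n):
        for v in range(8):
            for k in range(3):
                out[i, v, k] = (
                    pos[i, k]
                    + R[i, k, 0] * signs[v, 0] * half[i, 0]
                    + R[i, k, 1] * signs[v, 1] * half[i, 1]
                    + R[i, k, 2] * signs[v, 2] * half[i, 2]
                )


@njit(cache=True)
def _sat_separation(pos_i, R_i, half_i, pos_j, R_j, half_j):
    """Minimum-penetration axis over the 15 SAT axes.

    Returns (sep, axis[3], code): the largest separation (negative =
    penetration depth of the least-overlapping axis), the axis in world
    frame oriented from body j toward body i, and the feature code
    (0-2 face of i, 3-5 face of j, 6-14 edge pair 3*ci+cj+6).  Face axes get
    a small preference over edge axes to stabilise manifold selection.
    """
    d = np.empty(3)
    for k in range(3):
        d[k] = pos_i[k] - pos_j[k]

    best_sep = -1.0e30
    best = np.empty(3)
    best[0] = 0.0
    best[1] = 0.0
    best[2] = 1.0
    code = 0

    for src in range(2):
        for c in range(3):
            ax = R_i[0, c] if src == 0 else R_j[0, c]
            ay = R_i[1, c] if src == 0 else R_j[1, c]
            az = R_i[2, c] if src == 0 else R_j[2, c]
            ri = 0.0
            rj = 0.0
            for k in range(3):
                ri += half_i[k] * abs(ax * R_i[0, k] + ay * R_i[1, k] + az * R_i[2, k])
                rj += half_j[k] * abs(ax * R_j[0, k] + ay * R_j[1, k] + az * R_j[2, k])
            dist = ax * d[0] + ay * d[1] + az * d[2]
            sep = abs(dist) - (ri + rj)
            if sep > best_sep:
                best_sep = sep
                code = 3 * src + c
                if dist < 0.0:
                    best[0], best[1], best[2] = -ax, -ay, -az
                else:
                    best[0], best[1], best[2] = ax, ay, az

    # cross-product (edge-edge) axes; require a clear win over face axes
    edge_bias = 1.0e-5
    for ci in range(3):
        for cj in range(3):
            ex, ey, ez = R_i[0, ci], R_i[1, ci], R_i[2, ci]
            fx, fy, fz = R_j[0, cj], R_j[1, cj], R_j[2, cj]
            ax = ey * fz - ez * fy
            ay = ez * fx - ex * fz
            az = ex * fy - ey * fx
            norm = (ax * ax + ay * ay + az * az) ** 0.5
            if norm < 1.0e-9:
                continue
            ax /= norm
            ay /= norm
            az /= norm
            ri = 0.0
            rj = 0.0
            for k in range(3):
                ri += half_i[k] * abs(ax * R_i[0, k] + ay * R_i[1, k] + az * R_i[2, k])
                rj += half_j[k] * abs(ax * R_j[0, k] + ay * R_j[1, k] + az * R_j[2, k])
            dist = ax * d[0] + ay * d[1] + az * d[2]
            sep = abs(dist) - (ri + rj)
            if sep > best_sep + edge_bias:
                best_sep = sep
                code = 6 + 3 * ci + cj
                if dist < 0.0:
                    best[0], best[1], best[2] = -ax, -ay, -az
                else:
                    best[0], best[1], best[2] = ax, ay, az

    return best_sep, best, code


@njit(cache=True)
def _clip_face_contacts(
    pos_r, R_r, half_r, pos_o, R_o, half_o, axis, ref_is_a, margin, pts, seps
):
    """Reference-face clipping manifold for a face-feature SAT axis.

    ``axis`` points from body j toward body i; ``ref_is_a`` says whether the
    reference box is body i.  The incident face of the other box is clipped
    against the side planes of the reference face; points at most ``margin``
    above the face are kept.  Returns the number of points written to
    pts/seps (max 8).
    """
    # outward normal of the reference face: toward the other box
    if ref_is_a:
        nrx, nry, nrz = -axis[0], -axis[1], -axis[2]
    else:
        nrx, nry, nrz = axis[0], axis[1], axis[2]

    # reference face axis: the box axis most parallel to n_ref
    bestdot = -2.0
    rc = 0
    rs = 1.0
    for c in range(3):
        dt = nrx * R_r[0, c] + nry * R_r[1, c] + nrz * R_r[2, c]
        if abs(dt) > bestdot:
            bestdot = abs(dt)
            rc = c
            rs = 1.0 if dt >= 0.0 else -1.0
    fc = np.empty(3)  # reference face center
    for k in range(3):
        fc[k] = pos_r[k] + rs * half_r[rc] * R_r[k, rc]
    # face plane outward normal (exactly aligned with the box face)
    fn = np.empty(3)
    for k in range(3):
        fn[k] = rs * R_r[k, rc]
    # side-plane axes
    c1 = (rc + 1) % 3
    c2 = (rc + 2) % 3

    # incident face on the other box: most anti-parallel to fn
    bestdot = 2.0
    ic = 0
    isg = 1.0
    for c in range(3):
        dt = fn[0] * R_o[0, c] + fn[1] * R_o[1, c] + fn[2] * R_o[2, c]
        if dt < bestdot:
            bestdot = dt
            ic = c
            isg = 1.0
        if -dt < bestdot:
            bestdot = -dt
            ic = c
            isg = -1.0
    i1 = (ic + 1) % 3
    i2 = (ic + 2) % 3

    poly = np.empty((16, 3))
    tmp = np.empty((16, 3))
    # incident face corners in order
    su = (1.0, 1.0, -1.0, -1.0)
    sv = (1.0, -1.0, -1.0, 1.0)
    for v in range(4):
        for k in range(3):
            poly[v, k] = (
                pos_o[k]
                + isg * half_o[ic] * R_o[k, ic]
                + su[v] * half_o[i1] * R_o[k, i1]
                + sv[v] * half_o[i2] * R_o[k, i2]
            )
    nv = 4

    # clip against the 4 side planes: |(p - fc) . d| <= h
    for plane in range(4):
        cidx = c1 if plane < 2 else c2
        sgn = 1.0 if plane % 2 == 0 else -1.0
        h = half_r[cidx]
        nout = 0
        for v in range(nv):
            p0 = poly[v]
            p1 = poly[(v + 1) % nv]
            f0 = sgn * (
                (p0[0] - fc[0]) * R_r[0, cidx]
                + (p0[1] - fc[1]) * R_r[1, cidx]
                + (p0[2] - fc[2]) * R_r[2, cidx]
            ) - h
            f1 = sgn * (
                (p1[0] - fc[0]) * R_r[0, cidx]
                + (p1[1] - fc[1]) * R_r[1, cidx]
                + (p1[2] - fc[2]) * R_r[2, cidx]
            ) - h
            if f0 <= 0.0:
                for k in range(3):
                    tmp[nout, k] = p0[k]
                nout += 1
            if (f0 < 0.0 and f1 > 0.0) or (f0 > 0.0 and f1 < 0.0):
                t = f0 / (f0 - f1)
                for k in range(3):
                    tmp[nout, k] = p0[k] + t * (p1[k] - p0[k])
                nout += 1
            if nout >= 15:
                break
        nv = nout
        for v in range(nv):
            for k in range(3):
                poly[v, k] = tmp[v, k]
        if nv == 0:
            return 0

    # keep points at most margin above the reference face
    n_out = 0
    for v in range(nv):
        s = (
            (poly[v, 0] - fc[0]) * fn[0]
            + (poly[v, 1] - fc[1]) * fn[1]
            + (poly[v, 2] - fc[2]) * fn[2]
        )
        if s <= margin and n_out < 8:
            for k in range(3):
                pts[n_out, k] = poly[v, k]
            seps[n_out] = s
            n_out += 1
    return n_out


@njit(cache=True)
def _edge_edge_contact(pos_i, R_i, half_i, pos_j, R_j, half_j, axis, ci, cj, point):
    """Closest points of the two witness edges; writes the midpoint."""
    # witness edge on i: farthest in -axis (toward j)
    pa = np.empty(3)
    for k in range(3):
        pa[k] = pos_i[k]
    for c in range(3):
        if c == ci:
            continue
        dt = axis[0] * R_i[0, c] + axis[1] * R_i[1, c] + axis[2] * R_i[2, c]
        s = -1.0 if dt > 0.0 else 1.0
        for k in range(3):
            pa[k] += s * half_i[c] * R_i[k, c]
    pb = np.empty(3)
    for k in range(3):
        pb[k] = pos_j[k]
    for c in range(3):
        if c == cj:
            continue
        dt = axis[0] * R_j[0, c] + axis[1] * R_j[1, c] + axis[2] * R_j[2, c]
        s = 1.0 if dt > 0.0 else -1.0
        for k in range(3):
            pb[k] += s * half_j[c] * R_j[k, c]
    # closest points of the two segments pa +/- ha*u, pb +/- hb*v
    ux, uy, uz = R_i[0, ci], R_i[1, ci], R_i[2, ci]
    vx, vy, vz = R_j[0, cj], R_j[1, cj], R_j[2, cj]
    wx, wy, wz = pa[0] - pb[0], pa[1] - pb[1], pa[2] - pb[2]
    b = ux * vx + uy * vy + uz * vz
    d = ux * wx + uy * wy + uz * wz
    e = vx * wx + vy * wy + vz * wz
    denom = 1.0 - b * b
    if abs(denom) < 1.0e-9:
        s = 0.0
    else:
        s = (b * e - d) / denom
    ha, hb = half_i[ci], half_j[cj]
    if s > ha:
        s = ha
    elif s < -ha:
        s = -ha
    t = e + s * b
    if t > hb:
        t = hb
    elif t < -hb:
        t = -hb
    point[0] = 0.5 * (pa[0] + s * ux + pb[0] + t * vx)
    point[1] = 0.5 * (pa[1] + s * uy + pb[1] + t * vy)
    point[2] = 0.5 * (pa[2] + s * uz + pb[2] + t * vz)


@njit(cache=True)
def gen_contacts(pos, quat, half, margin, ca, cb, cp, cn, cs):
    """Fill contact buffers; returns the number of contacts.

    Ground contacts (b == -1) are vertices with z <= margin.  Box-box
    contacts use the SAT minimum axis: face features produce a clipped\n    reference-face manifold, edge features a single closest-point contact.
    """
    n = pos.shape[0]
    R = np.empty((n, 3, 3))
    all_rotations(quat, R)
    verts = np.empty((n, 8, 3))
    box_vertices(pos, R, half, _SIGNS, verts)

    # world AABB extents for the broad phase
    ext = np.empty((n, 3))
    for i in range(n):
        for k in range(3):
            e = 0.0
            for c in range(3):
                e += abs(R[i, k, c]) * half[i, c]
            ext[i, k] = e

    m = 0
    for i in range(n):
        for v in range(8):
            z = verts[i, v, 2]
            if z <= margin and m < ca.shape[0]:
                ca[m] = i
                cb[m] = -1
                cp[m, 0] = verts[i, v, 0]
                cp[m, 1] = verts[i, v, 1]
                cp[m, 2] = verts[i, v, 2]
                cn[m, 0] = 0.0
                cn[m, 1] = 0.0
                cn[m, 2] = 1.0
                cs[m] = z
                m += 1

    for i in range(n):
        for j in range(i + 1, n):
            ok = True
            for k in range(3):
                if abs(pos[i, k] - pos[j, k]) > ext[i, k] + ext[j, k] + margin:
                    ok = False
                    break
            if not ok:
                continue
            sep, axis, code = _sat_separation(pos[i], R[i], half[i], pos[j], R[j], half[j])
            if sep > margin:
                continue
            if code < 6:
                # face feature: reference-face clipping manifold
                pts = np.empty((8, 3))
                seps = np.empty(8)
                if code < 3:
                    npts = _clip_face_contacts(
                        pos[i], R[i], half[i], pos[j], R[j], half[j], axis, True, margin, pts, seps
                    )
                else:
                    npts = _clip_face_contacts(
                        pos[j], R[j], half[j], pos[i], R[i], half[i], axis, False, margin, pts, seps
                    )
                for v in range(npts):
                    if m >= ca.shape[0]:
                        break
                    ca[m] = i
                    cb[m] = j
                    for k in range(3):
                        cp[m, k] = pts[v, k]
                        cn[m, k] = axis[k]
                    cs[m] = seps[v]
                    m += 1
            elif m < ca.shape[0]:
                # edge-edge feature: single contact at the closest points
                point = np.empty(3)
                ci_ax = (code - 6) // 3
                cj_ax = (code - 6) % 3
                _edge_edge_contact(
                    pos[i], R[i], half[i], pos[j], R[j], half[j], axis, ci_ax, cj_ax, point
                )
                ca[m] = i
                cb[m] = j
                for k in range(3):
                    cp[m, k] = point[k]
                    cn[m, k] = axis[k]
                cs[m] = sep
                m += 1
    return m


@njit(cache=True)
def _apply_small_rotation(q, rx, ry, rz):
    # q <- normalize(dq * q), dq = (1, r/2)
    hw, hx, hy, hz = 1.0, 0.5 * rx, 0.5 * ry, 0.5 * rz
    w = hw * q[0] - hx * q[1] - hy * q[2] - hz * q[3]
    x = hw * q[1] + hx * q[0] + hy * q[3] - hz * q[2]
    y = hw * q[2] - hx * q[3] + hy * q[0] + hz * q[1]
    z = hw * q[3] + hx * q[2] - hy * q[1] + hz * q[0]
    norm = (w * w + x * x + y * y + z * z) ** 0.5
    q[0] = w / norm
    q[1] = x / norm
    q[2] = y / norm
    q[3] = z / norm


@njit(cache=True)
def step_dynamics(
    pos,
    quat,
    vel,
    omg,
    invm,
    invI_body,
    ca,
    cb,
    cp,
    cn,
    cs,
    nc,
    gravity,
    dt,
    mu,
    vel_iters,
    pos_iters,
    slop,
    beta,
    max_corr,
    accn_out,
):
    """One semi-implicit Euler step with sequential impulses.

    Velocity solve (restitution 0) -> integration -> split-impulse position
    correction.  ``accn_out`` receives the accumulated normal impulse per
    contact (used by the caller for wake-on-impact decisions).
    """
    n = pos.shape[0]
    R = np.empty((n, 3, 3))
    all_rotations(quat, R)
    invIw = np.zeros((n, 3, 3))
    for i in range(n):
        if invm[i] > 0.0:
            for r in range(3):
                for c in range(3):
                    s = 0.0
                    for k in range(3):
                        s += R[i, r, k] * invI_body[i, k] * R[i, c, k]
                    invIw[i, r, c] = s
            for k in range(3):
                vel[i, k] += gravity[k] * dt

    # contact precomputation
    ra = np.empty((nc, 3))
    rb = np.empty((nc, 3))
    t1 = np.empty((nc, 3))
    t2 = np.empty((nc, 3))
    kn = np.empty(nc)
    kt1 = np.empty(nc)
    kt2 = np.empty(nc)
    la = np.empty((nc, 3))  # local anchor on a (for position solve)
    lb = np.empty((nc, 3))
    accn = np.zeros(nc)
    acc1 = np.zeros(nc)
    acc2 = np.zeros(nc)

    for c in range(nc):
        a = ca[c]
        b = cb[c]
        for k in range(3):
            ra[c, k] = cp[c, k] - pos[a, k]
            rb[c, k] = cp[c, k] - (pos[b, k] if b >= 0 else 0.0)
        # local anchors (body frame)
        for k in range(3):
            s = 0.0
            for r in range(3):
                s += R[a, r, k] * ra[c, r]
            la[c, k] = s
        if b >= 0:
            for k in range(3):
                s = 0.0
                for r in range(3):
                    s += R[b, r, k] * rb[c, r]
                lb[c, k] = s
        # orthonormal tangent basis from the normal
        nx, ny, nz = cn[c, 0], cn[c, 1], cn[c, 2]
        if abs(nz) < 0.9:
            # t1 = n x z-hat
            tx, ty, tz = ny, -nx, 0.0
        else:
            # n close to vertical: t1 = n x x-hat
            tx, ty, tz = 0.0, nz, -ny
        tn = (tx * tx + ty * ty + tz * tz) ** 0.5
        t1[c, 0] = tx / tn
        t1[c, 1] = ty / tn
        t1[c, 2] = tz / tn
        t2[c, 0] = ny * t1[c, 2] - nz * t1[c, 1]
        t2[c, 1] = nz * t1[c, 0] - nx * t1[c, 2]
        t2[c, 2] = nx * t1[c, 1] - ny * t1[c, 0]

        # effective masses for n, t1, t2
        for which in range(3):
            if which == 0:
                dx, dy, dz = nx, ny, nz
            elif which == 1:
                dx, dy, dz = t1[c, 0], t1[c, 1], t1[c, 2]
            else:
                dx, dy, dz = t2[c, 0], t2[c, 1], t2[c, 2]
            k_eff = invm[a] + (invm[b] if b >= 0 else 0.0)
            # rotational term for a
            cxa = ra[c, 1] * dz - ra[c, 2] * dy
            cya = ra[c, 2] * dx - ra[c, 0] * dz
            cza = ra[c, 0] * dy - ra[c, 1] * dx
            ix = invIw[a, 0, 0] * cxa + invIw[a, 0, 1] * cya + invIw[a, 0, 2] * cza
            iy = invIw[a, 1, 0] * cxa + invIw[a, 1, 1] * cya + invIw[a, 1, 2] * cza
            iz = invIw[a, 2, 0] * cxa + invIw[a, 2, 1] * cya + invIw[a, 2, 2] * cza
            # (r x d) . Iinv (r x d)
            k_eff += ix * cxa + iy * cya + iz * cza
            if b >= 0:
                cxb = rb[c, 1] * dz - rb[c, 2] * dy
                cyb = rb[c, 2] * dx - rb[c, 0] * dz
                czb = rb[c, 0] * dy - rb[c, 1] * dx
                jx = invIw[b, 0, 0] * cxb + invIw[b, 0, 1] * cyb + invIw[b, 0, 2] * czb
                jy = invIw[b, 1, 0] * cxb + invIw[b, 1, 1] * cyb + invIw[b, 1, 2] * czb
                jz = invIw[b, 2, 0] * cxb + invIw[b, 2, 1] * cyb + invIw[b, 2, 2] * czb
                k_eff += jx * cxb + jy * cyb + jz * czb
            if k_eff < 1.0e-12:
                k_eff = 1.0e-12
            if which == 0:
                kn[c] = k_eff
            elif which == 1:
                kt1[c] = k_eff
            else:
                kt2[c] = k_eff

    # velocity iterations
    for _ in range(vel_iters):
        for c in range(nc):
            a = ca[c]
            b = cb[c]
            # relative velocity at contact: va + wa x ra - (vb + wb x rb)
            rvx = vel[a, 0] + omg[a, 1] * ra[c, 2] - omg[a, 2] * ra[c, 1]
            rvy = vel[a, 1] + omg[a, 2] * ra[c, 0] - omg[a, 0] * ra[c, 2]
            rvz = vel[a, 2] + omg[a, 0] * ra[c, 1] - omg[a, 1] * ra[c, 0]
            if b >= 0:
                rvx -= vel[b, 0] + omg[b, 1] * rb[c, 2] - omg[b, 2] * rb[c, 1]
                rvy -= vel[b, 1] + omg[b, 2] * rb[c, 0] - omg[b, 0] * rb[c, 2]
                rvz -= vel[b, 2] + omg[b, 0] * rb[c, 1] - omg[b, 1] * rb[c, 0]
            vn = rvx * cn[c, 0] + rvy * cn[c, 1] + rvz * cn[c, 2]
            dl = -vn / kn[c]
            new = accn[c] + dl
            if new < 0.0:
                new = 0.0
            dl = new - accn[c]
            accn[c] = new
            px = dl * cn[c, 0]
            py = dl * cn[c, 1]
            pz = dl * cn[c, 2]
            _apply_impulse(pos, vel, omg, invm, invIw, a, ra[c], px, py, pz, 1.0)
            if b >= 0:
                _apply_impulse(pos, vel, omg, invm, invIw, b, rb[c], px, py, pz, -1.0)

            # friction (box clamp against accumulated normal impulse)
            hi = mu * accn[c]
            for which in range(2):
                td = t1[c] if which == 0 else t2[c]
                kt = kt1[c] if which == 0 else kt2[c]
                rvx = vel[a, 0] + omg[a, 1] * ra[c, 2] - omg[a, 2] * ra[c, 1]
                rvy = vel[a, 1] + omg[a, 2] * ra[c, 0] - omg[a, 0] * ra[c, 2]
                rvz = vel[a, 2] + omg[a, 0] * ra[c, 1] - omg[a, 1] * ra[c, 0]
                if b >= 0:
                    rvx -= vel[b, 0] + omg[b, 1] * rb[c, 2] - omg[b, 2] * rb[c, 1]
                    rvy -= vel[b, 1] + omg[b, 2] * rb[c, 0] - omg[b, 0] * rb[c, 2]
                    rvz -= vel[b, 2] + omg[b, 0] * rb[c, 1] - omg[b, 1] * rb[c, 0]
                vt = rvx * td[0] + rvy * td[1] + rvz * td[2]
                dl = -vt / kt
                acc = acc1[c] if which == 0 else acc2[c]
                new = acc + dl
                if new > hi:
                    new = hi
                elif new < -hi:
                    new = -hi
                dl = new - acc
                if which == 0:
                    acc1[c] = new
                else:
                    acc2[c] = new
                px = dl * td[0]
                py = dl * td[1]
                pz = dl * td[2]
                _apply_impulse(pos, vel, omg, invm, invIw, a, ra[c], px, py, pz, 1.0)
                if b >= 0:
                    _apply_impulse(pos, vel, omg, invm, invIw, b, rb[c], px, py, pz, -1.0)

    # integrate dynamic bodies
    for i in range(n):
        if invm[i] > 0.0:
            for k in range(3):
                pos[i, k] += vel[i, k] * dt
            _apply_small_rotation(quat[i], omg[i, 0] * dt, omg[i, 1] * dt, omg[i, 2] * dt)

    # split-impulse position correction
    for _ in range(pos_iters):
        all_rotations(quat, R)
        for c in range(nc):
            a = ca[c]
            b = cb[c]
            # world anchors from local anchors
            wax = pos[a, 0] + R[a, 0, 0] * la[c, 0] + R[a, 0, 1] * la[c, 1] + R[a, 0, 2] * la[c, 2]
            way = pos[a, 1] + R[a, 1, 0] * la[c, 0] + R[a, 1, 1] * la[c, 1] + R[a, 1, 2] * la[c, 2]
            waz = pos[a, 2] + R[a, 2, 0] * la[c, 0] + R[a, 2, 1] * la[c, 1] + R[a, 2, 2] * la[c, 2]
            if b >= 0:
                wbx = pos[b, 0] + R[b, 0, 0] * lb[c, 0] + R[b, 0, 1] * lb[c, 1] + R[b, 0, 2] * lb[c, 2]
                wby = pos[b, 1] + R[b, 1, 0] * lb[c, 0] + R[b, 1, 1] * lb[c, 1] + R[b, 1, 2] * lb[c, 2]
                wbz = pos[b, 2] + R[b, 2, 0] * lb[c, 0] + R[b, 2, 1] * lb[c, 1] + R[b, 2, 2] * lb[c, 2]
            else:
                # ground anchor never moves
                wbx, wby, wbz = cp[c, 0], cp[c, 1], cp[c, 2]
            # both anchors coincide at cp at detection time, so the change in
            # separation is the relative anchor displacement along the normal
            s_now = cs[c] + (wax - wbx) * cn[c, 0] + (way - wby) * cn[c, 1] + (waz - wbz) * cn[c, 2]
            if s_now < -slop:
                corr = beta * (-slop - s_now)
                if corr > max_corr:
                    corr = max_corr
                p = corr / kn[c]
                px = p * cn[c, 0]
                py = p * cn[c, 1]
                pz = p * cn[c, 2]
                if invm[a] > 0.0:
                    pos[a, 0] += invm[a] * px
                    pos[a, 1] += invm[a] * py
                    pos[a, 2] += invm[a] * pz
                    cxa = ra[c, 1] * pz - ra[c, 2] * py
                    cya = ra[c, 2] * px - ra[c, 0] * pz
                    cza = ra[c, 0] * py - ra[c, 1] * px
                    rx = invIw[a, 0, 0] * cxa + invIw[a, 0, 1] * cya + invIw[a, 0, 2] * cza
                    ry = invIw[a, 1, 0] * cxa + invIw[a, 1, 1] * cya + invIw[a, 1, 2] * cza
                    rz = invIw[a, 2, 0] * cxa + invIw[a, 2, 1] * cya + invIw[a, 2, 2] * cza
                    _apply_small_rotation(quat[a], rx, ry, rz)
                if b >= 0 and invm[b] > 0.0:
                    pos[b, 0] -= invm[b] * px
                    pos[b, 1] -= invm[b] * py
                    pos[b, 2] -= invm[b] * pz
                    cxb = rb[c, 1] * pz - rb[c, 2] * py
                    cyb = rb[c, 2] * px - rb[c, 0] * pz
                    czb = rb[c, 0] * py - rb[c, 1] * px
                    rx = invIw[b, 0, 0] * cxb + invIw[b, 0, 1] * cyb + invIw[b, 0, 2] * czb
                    ry = invIw[b, 1, 0] * cxb + invIw[b, 1, 1] * cyb + invIw[b, 1, 2] * czb
                    rz = invIw[b, 2, 0] * cxb + invIw[b, 2, 1] * cyb + invIw[b, 2, 2] * czb
                    _apply_small_rotation(quat[b], -rx, -ry, -rz)

    for c in range(nc):
        accn_out[c] = accn[c]


@njit(cache=True)
def _apply_impulse(pos, vel, omg, invm, invIw, i, r, px, py, pz, sign):
    if invm[i] <= 0.0:
        return
    vel[i, 0] += sign * invm[i] * px
    vel[i, 1] += sign * invm[i] * py
    vel[i, 2] += sign * invm[i] * pz
    cx = r[1] * pz - r[2] * py
    cy = r[2] * px - r[0] * pz
    cz = r[0] * py - r[1] * px
    omg[i, 0] += sign * (invIw[i, 0, 0] * cx + invIw[i, 0, 1] * cy + invIw[i, 0, 2] * cz)
    omg[i, 1] += sign * (invIw[i, 1, 0] * cx + invIw[i, 1, 1] * cy + invIw[i, 1, 2] * cz)
    omg[i, 2] += sign * (invIw[i, 2, 0] * cx + invIw[i, 2, 1] * cy + invIw[i, 2, 2] * cz)


@njit(cache=True)
def vertices_snapshot(pos, quat, half, out):
    """Convenience wrapper used when recording trajectory stages."""
    n = pos.shape[0]
    R = np.empty((n, 3, 3))
    all_rotations(quat, R)
    box_vertices(pos, R, half, _SIGNS, out)
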