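"""Static equilibrium of a contacting island of rigid boxes.

A set of resting bodies stays at rest iff there exist contact forces --
non-negative normal components plus Coulomb friction -- that balance gravity
on every body.  That existence question is a linear program once the friction
cone is replaced by a polyhedral pyramid.  We minimise the L1 norm of the
force/torque residuals; the island is in equilibrium when the optimum is
(numerically) zero.

Solving statics exactly instead of relying on the impulse solver's resting
behaviour guarantees that a stable stack shows *zero* displacement, which is
what the displacement criterion with a 0.01 j.n.d. needs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

# 4-direction friction pyramid (the usual engine linearization); tangential
# capacity varies with direction between mu and mu/sqrt(2), which averages
# out over the uniformly distributed horizontal gravity orientations used
# throughout
_N_PYR = 4
_PYR_ANGLES = np.arange(_N_PYR) * (2.0 * np.pi / _N_PYR)


def _tangent_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if abs(n[2]) < 0.9:
        t1 = np.array([n[1], -n[0], 0.0])
    else:
        t1 = np.array([0.0, n[2], -n[1]])
    t1 /= np.sqrt(t1 @ t1)
    t2 = np.array(
        [
            n[1] * t1[2] - n[2] * t1[1],
            n[2] * t1[0] - n[0] * t1[2],
            n[0] * t1[1] - n[1] * t1[0],
        ]
    )
    return t1, t2


def equilibrium_feasible(
    coms: np.ndarray,
    masses: np.ndarray,
    contacts: list[tuple[int, int, np.ndarray, np.ndarray]],
    gravity: np.ndarray,
    mu: float,
    tol_scale: float = 1e-6,
) -> bool:
    """True if contact forces within the friction pyramid can balance gravity.

    Parameters
    ----------
    coms, masses : island body centres of mass (nb, 3) and masses (nb,).
    contacts : (a, b, point, normal) tuples with island-local indices;
        b == -1 means the static environment; the normal points from b to a.
    gravity : acceleration vector applied to every body.
    mu : friction coefficient.
    """
    nb = coms.shape[0]
    g = np.asarray(gravity, dtype=float)
    if not contacts:
        return False

    nvar_c = 1 + _N_PYR  # normal magnitude + pyramid coefficients
    m = len(contacts)
    n_eq = 6 * nb
    nvar = nvar_c * m

    A_eq = np.zeros((n_eq, nvar))
    b_eq = np.zeros(n_eq)
    for i in range(nb):
        b_eq[6 * i : 6 * i + 3] = -masses[i] * g  # sum(F) = -m g

    A_ub = np.zeros((m, nvar))  # sum(beta) - mu * lam <= 0

    cosk = np.cos(_PYR_ANGLES)
    sink = np.sin(_PYR_ANGLES)
    for c, (a, b, p, n) in enumerate(contacts):
        t1, t2 = _tangent_basis(n)
        dirs = np.empty((nvar_c, 3))
        dirs[0] = n
        dirs[1:] = cosk[:, None] * t1 + sink[:, None] * t2
        col0 = nvar_c * c
        for side, body in ((1.0, a), (-1.0, b)):
            if body < 0:
                continue
            r = p - coms[body]
            # torque arm r x dirs[k], vectorized over k
            tq = np.empty((nvar_c, 3))
            tq[:, 0] = r[1] * dirs[:, 2] - r[2] * dirs[:, 1]
            tq[:, 1] = r[2] * dirs[:, 0] - r[0] * dirs[:, 2]
            tq[:, 2] = r[0] * dirs[:, 1] - r[1] * dirs[:, 0]
            A_eq[6 * body : 6 * body + 3, col0 : col0 + nvar_c] += side * dirs.T
            A_eq[6 * body + 3 : 6 * body + 6, col0 : col0 + nvar_c] += side * tq.T
        A_ub[c, col0] = -mu
        A_ub[c, col0 + 1 : col0 + nvar_c] = 1.0

    # pure feasibility form: the balance equations are relaxed to a band of
    # width tol, so any solution within the band certifies equilibrium
    tol = tol_scale * float(np.sum(masses)) * (np.linalg.norm(g) + 1.0)
    A_all = np.vstack([A_ub, A_eq, -A_eq])
    b_all = np.concatenate([np.zeros(m), b_eq + tol, -b_eq + tol])
    res = linprog(np.zeros(nvar), A_ub=A_all, b_ub=b_all, method="highs")
    return bool(res.status == 0)


def quick_infeasible(
    has_ground: bool,
    gravity: np.ndarray,
    mu: float,
) -> bool:
    """Cheap certain-infeasibility screen for islands whose only external
    support is the ground plane (normal +z).

    Aggregate force balance requires the ground to push the island's total
    weight upward (so gravity must point down) and friction to cancel the
    tangential component (|g_t| <= mu |g_z|).  Torque balance still needs the
    LP, so a ``False`` here is *not* a feasibility certificate.
    """
    if not has_ground:
        return True
    gz = gravity[2]
    if gz >= 0.0:
        return True
    gt = float(np.hypot(gravity[0], gravity[1]))
    return gt > mu * abs(gz) + 1e-12
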