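"""Forward simulation world: boxes + ground plane + uniform gravity.

The stepping scheme is equilibrium-preserving: every body starts asleep, and
a sleeping island only wakes when the static-equilibrium test (statics.py)
proves that no admissible contact forces can hold it, or when a moving body
slams into it.  Sleeping bodies do not move at all, so a stable stack yields
a bit-for-bit constant trajectory; awake bodies are integrated with a
sequential-impulse solver (kernels.py).  Gravity is the only external force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .statics import equilibrium_feasible, quick_infeasible


@dataclass(frozen=True)
class EngineParams:
    """Numerical parameters of the rigid-body backend.

    Defaults are tuned for 0.4-unit boxes at dt = 1/240 s; lengths are in the
    same arbitrary units as the block geometry.
    """

    dt: float = 1.0 / 240.0
    friction: float = 1.0
    restitution: float = 0.0  # kept for the record; the solver never bounces
    margin: float = 5e-4  # contact detection tolerance
    slop: float = 2e-4  # allowed penetration before position correction
    vel_iters: int = 12
    pos_iters: int = 2
    beta: float = 0.25  # position-correction gain per iteration
    max_corr: float = 0.02  # max positional correction per contact/iteration
    sleep_lin: float = 0.01  # linear speed below which a body may sleep
    sleep_ang: float = 0.05  # angular speed threshold
    sleep_steps: int = 8  # consecutive quiet steps before sleeping
    wake_impulse: float = 0.01  # N*s on a sleeping body that forces a wake


class World:
    """Mutable simulation state for one stack under one gravity vector."""

    def __init__(
        self,
        centers: np.ndarray,
        half_extents: np.ndarray,
        masses: np.ndarray,
        gravity: np.ndarray,
        params: EngineParams | None = None,
    ):
        self.params = params or EngineParams()
        self.n = centers.shape[0]
        self.pos = np.array(centers, dtype=np.float64)
        self.quat = np.zeros((self.n, 4))
        self.quat[:, 0] = 1.0
        self.vel = np.zeros((self.n, 3))
        self.omg = np.zeros((self.n, 3))
        self.half = np.array(half_extents, dtype=np.float64)
        self.mass = np.array(masses, dtype=np.float64)
        full = 2.0 * self.half
        inertia = (
            self.mass[:, None]
            / 12.0
            * np.stack(
                [
                    full[:, 1] ** 2 + full[:, 2] ** 2,
                    full[:, 0] ** 2 + full[:, 2] ** 2,
                    full[:, 0] ** 2 + full[:, 1] ** 2,
                ],
                axis=1,
            )
        )
        self.invI_body = 1.0 / inertia
        self.gravity = np.asarray(gravity, dtype=np.float64)
        self._invm_awake = 1.0 / self.mass

        self.awake = np.zeros(self.n, dtype=bool)
        self.dirty = np.ones(self.n, dtype=bool)
        self.sleep_count = np.zeros(self.n, dtype=np.int64)
        self.fail_count = np.zeros(self.n, dtype=np.int64)
        self.trust_rest = np.zeros(self.n, dtype=bool)
        self.recent_sleep = np.zeros(self.n, dtype=np.int64)
        # bitmask per body of its *sleeping* contact partners (bit n = ground);
        # only changes here can alter a sleeping island's equilibrium
        self._prev_support = np.full(self.n, -1, dtype=np.int64)

        cap = kernels.MAX_CONTACTS
        self._ca = np.zeros(cap, dtype=np.int64)
        self._cb = np.zeros(cap, dtype=np.int64)
        self._cp = np.zeros((cap, 3))
        self._cn = np.zeros((cap, 3))
        self._cs = np.zeros(cap)
        self._accn = np.zeros(cap)

    # ------------------------------------------------------------------
    def _sleeping_islands(self, nc: int) -> list[list[int]]:
        """Connected components of *sleeping* bodies via body-body contacts."""
        parent = list(range(self.n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for c in range(nc):
            a, b = self._ca[c], self._cb[c]
            if b >= 0 and not self.awake[a] and not self.awake[b]:
                ra, rb = find(int(a)), find(int(b))
                if ra != rb:
                    parent[ra] = rb
        groups: dict[int, list[int]] = {}
        for i in range(self.n):
            if not self.awake[i]:
                groups.setdefault(find(i), []).append(i)
        return list(groups.values())

    def _check_statics(self, nc: int) -> None:
        p = self.params
        for island in self._sleeping_islands(nc):
            members = set(island)
            if not any(self.dirty[i] for i in island):
                continue
            if all(self.trust_rest[i] for i in island if self.dirty[i]):
                # dynamics already showed this island rests here; stop
                # re-litigating until its contact topology changes
                for i in island:
                    self.dirty[i] = False
                continue
            local = {b: k for k, b in enumerate(island)}
            contacts = []
            has_ground = False
            for c in range(nc):
                a, b = int(self._ca[c]), int(self._cb[c])
                if a in members and (b == -1 or b in members):
                    if b == -1:
                        has_ground = True
                    contacts.append(
                        (local[a], -1 if b == -1 else local[b], self._cp[c].copy(), self._cn[c].copy())
                    )
            feasible = False
            if contacts and not quick_infeasible(has_ground, self.gravity, p.friction):
                feasible = equilibrium_feasible(
                    self.pos[island],
                    self.mass[island],
                    contacts,
                    self.gravity,
                    p.friction,
                )
            if feasible:
                for i in island:
                    self.dirty[i] = False
            else:
                for i in island:
                    self.awake[i] = True
                    self.dirty[i] = False
                    self.sleep_count[i] = 0
                    if self.recent_sleep[i] > 0:
                        # it just came to rest dynamically; statics disagrees
                        # (usually a contact manifold the LP can't see) --
                        # trust the dynamics and stop waking it
                        self.fail_count[i] += 1
                        if self.fail_count[i] >= 1:
                            self.trust_rest[i] = True

    # ------------------------------------------------------------------
    def step(self) -> bool:
        """Advance one stage; returns False when the scene is fully static."""
        p = self.params
        if not self.awake.any() and not self.dirty.any():
            return False

        nc = kernels.gen_contacts(
            self.pos, self.quat, self.half, p.margin, self._ca, self._cb, self._cp, self._cn, self._cs
        )
        ca = self._ca[:nc]
        cb = self._cb[:nc]
        all_awake = bool(self.awake.all())

        if not all_awake:
            # support-topology bookkeeping: which sleeping bodies / ground
            # each sleeping body touches; awake neighbors do not hold
            # anything up, so their churn never triggers a statics re-check
            support = np.zeros(self.n, dtype=np.int64)
            asleep = ~self.awake
            ground_c = cb == -1
            np.bitwise_or.at(support, ca[ground_c & asleep[ca]], 1 << self.n)
            bb = ~ground_c
            a_bb, b_bb = ca[bb], cb[bb]
            both = asleep[a_bb] & asleep[b_bb]
            np.bitwise_or.at(support, a_bb[both], 1 << b_bb[both].astype(np.int64))
            np.bitwise_or.at(support, b_bb[both], 1 << a_bb[both].astype(np.int64))
            support[self.awake] = -1
            # a just-slept body transitions from the awake sentinel (-1) to
            # its first support mask; that is not a support *change* -- its
            # rest was just established dynamically.  Changes to an existing
            # sleeping mask (a neighbor slept onto it, woke, or slid away)
            # do re-open the equilibrium question for the island.
            changed = (support != self._prev_support) & (self._prev_support != -1)
            self.dirty |= changed & asleep
            self.trust_rest[changed] = False
            self.fail_count[changed] = 0
            self._prev_support = support

            self._check_statics(nc)
            all_awake = bool(self.awake.all())

        if self.awake.any():
            if all_awake:
                invm = self._invm_awake
                cak, cbk = ca, cb
                cp, cn, cs = self._cp[:nc], self._cn[:nc], self._cs[:nc]
                nck = nc
            else:
                invm = np.where(self.awake, 1.0 / self.mass, 0.0)
                # keep only contacts touching an awake body; sleeping bodies
                # are pinned (invm 0) and appear as static colliders
                keep = self.awake[ca].copy()
                valid_b = cb >= 0
                keep[valid_b] |= self.awake[cb[valid_b]]
                idx = np.flatnonzero(keep)
                nck = idx.size
                cak = self._ca[idx]
                cbk = self._cb[idx]
                cp = self._cp[idx]
                cn = self._cn[idx]
                cs = self._cs[idx]
            if nck > 0:
                accn = np.zeros(nck)
                kernels.step_dynamics(
                    self.pos,
                    self.quat,
                    self.vel,
                    self.omg,
                    invm,
                    self.invI_body,
                    cak,
                    cbk,
                    cp,
                    cn,
                    cs,
                    nck,
                    self.gravity,
                    p.dt,
                    p.friction,
                    p.vel_iters,
                    p.pos_iters,
                    p.slop,
                    p.beta,
                    p.max_corr,
                    accn,
                )
                # wake-on-impact
                if not all_awake:
                    hits = np.flatnonzero(accn > p.wake_impulse)
                    for k in hits:
                        for body in (int(cak[k]), int(cbk[k])):
                            if body >= 0 and not self.awake[body]:
                                self.awake[body] = True
                                self.sleep_count[body] = 0
                                self.trust_rest[body] = False
                                self.fail_count[body] = 0
            else:
                # free bodies with no contacts at all: pure ballistic step
                dyn = self.awake
                self.vel[dyn] += self.gravity * p.dt
                self.pos[dyn] += self.vel[dyn] * p.dt
                for i in np.flatnonzero(dyn):
                    kernels._apply_small_rotation(
                        self.quat[i], self.omg[i, 0] * p.dt, self.omg[i, 1] * p.dt, self.omg[i, 2] * p.dt
                    )

        # sleep bookkeeping (vectorized over awake bodies)
        self.recent_sleep[self.recent_sleep > 0] -= 1
        aw = self.awake
        speed2 = np.einsum("ij,ij->i", self.vel, self.vel)
        wspeed2 = np.einsum("ij,ij->i", self.omg, self.omg)
        quiet = aw & (speed2 < p.sleep_lin**2) & (wspeed2 < p.sleep_ang**2)
        self.sleep_count[quiet] += 1
        self.sleep_count[aw & ~quiet] = 0
        fast = aw & (speed2 > (10.0 * p.sleep_lin) ** 2)
        self.fail_count[fast] = 0
        self.trust_rest[fast] = False
        # whole-island sleeping: a body may only sleep when every awake body
        # it (transitively) touches is quiet too, so a settling pile goes to
        # sleep as one unit and is statics-checked once
        ready = aw & (self.sleep_count >= p.sleep_steps)
        to_sleep = ready.copy()
        if ready.any():
            parent = list(range(self.n))

            def find(x: int) -> int:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for c in range(nc):
                a, b = int(ca[c]), int(cb[c])
                if b >= 0 and aw[a] and aw[b]:
                    raf, rbf = find(a), find(b)
                    if raf != rbf:
                        parent[raf] = rbf
            roots = np.array([find(i) for i in range(self.n)])
            for r in np.unique(roots[ready]):
                members = aw & (roots == r)
                if not ready[members].all():
                    to_sleep[members] = False
        if to_sleep.any():
            self.awake[to_sleep] = False
            self.vel[to_sleep] = 0.0
            self.omg[to_sleep] = 0.0
            self.sleep_count[to_sleep] = 0
            # dynamics brought these bodies to rest: trust that verdict (the
            # statics LP re-checks only once the contact topology changes)
            self.dirty[to_sleep] = False
            self.trust_rest[to_sleep] = True
            self.recent_sleep[to_sleep] = 3
            # bodies that were already asleep now carry a new load: re-open
            # their island's equilibrium question
            for c in range(nc):
                a, b = int(ca[c]), int(cb[c])
                if b >= 0:
                    if to_sleep[a] and not self.awake[b] and not to_sleep[b]:
                        self.dirty[b] = True
                        self.trust_rest[b] = False
                    elif to_sleep[b] and not self.awake[a] and not to_sleep[a]:
                        self.dirty[a] = True
                        self.trust_rest[a] = False
        return True

    # ------------------------------------------------------------------
    def settles_unmoved(self, eps: float, n_stages: int) -> bool:
        """True iff no body center moves ``eps`` within ``n_stages`` stages.

        Equivalent to running the full horizon and checking every stage, but
        exits as soon as the displacement bound is crossed or the scene goes
        fully static -- the cheap path for stable/unstable labeling.
        """
        pos0 = self.pos.copy()
        eps2 = eps * eps
        for _ in range(1, int(n_stages)):
            moved = self.step()
            d2 = np.einsum("ij,ij->i", self.pos - pos0, self.pos - pos0)
            if d2.max() >= eps2:
                return False
            if not moved:
                break
        return True

    # ------------------------------------------------------------------
    def run(self, n_stages: int) -> tuple[np.ndarray, np.ndarray]:
        """Record ``n_stages`` stages (stage 0 = initial state).

        Returns (centers [T,M,3], quats [T,M,4]).
        """
        T = int(n_stages)
        pos_hist = np.empty((T, self.n, 3))
        quat_hist = np.empty((T, self.n, 4))
        pos_hist[0] = self.pos
        quat_hist[0] = self.quat
        for t in range(1, T):
            moved = self.step()
            if not moved:
                pos_hist[t:] = self.pos
                quat_hist[t:] = self.quat
                break
            pos_hist[t] = self.pos
            quat_hist[t] = self.quat
        return pos_hist, quat_hist
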