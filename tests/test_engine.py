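import numpy as np

from gravistoch.engine import EngineParams, World, equilibrium_feasible
from gravistoch.engine import kernels


def _contacts(pos, quat, half, margin=5e-4):
    cap = kernels.MAX_CONTACTS
    ca = np.zeros(cap, dtype=np.int64)
    cb = np.zeros(cap, dtype=np.int64)
    cp = np.zeros((cap, 3))
    cn = np.zeros((cap, 3))
    cs = np.zeros(cap)
    nc = kernels.gen_contacts(pos, quat, half, margin, ca, cb, cp, cn, cs)
    return nc, ca[:nc], cb[:nc], cp[:nc], cn[:nc], cs[:nc]


def _identity_quats(n):
    q = np.zeros((n, 4))
    q[:, 0] = 1.0
    return q


def test_ground_contact_manifold_of_resting_box():
    pos = np.array([[0.0, 0.0, 0.2]])
    half = np.array([[0.6, 0.2, 0.2]])
    nc, ca, cb, cp, cn, cs = _contacts(pos, _identity_quats(1), half)
    assert nc == 4
    assert (cb == -1).all()
    assert np.allclose(cn, [0, 0, 1])
    assert np.allclose(cs, 0.0, atol=1e-12)


def test_crossing_boxes_get_face_manifold():
    # long-y box resting across a long-x box: no vertex of either lies inside
    # the other, so the manifold must come from face clipping
    pos = np.array([[0.0, 0.0, 0.2], [0.05, 0.0, 0.6]])
    half = np.array([[0.6, 0.2, 0.2], [0.2, 0.6, 0.2]])
    nc, ca, cb, cp, cn, cs = _contacts(pos, _identity_quats(2), half)
    pair = [k for k in range(nc) if cb[k] >= 0]
    assert len(pair) == 4  # the overlap rectangle's corners
    pts = cp[pair]
    assert np.allclose(pts[:, 2], 0.4, atol=1e-9)  # on the interface plane
    assert np.allclose(sorted(np.round(pts[:, 1], 6)), [-0.2, -0.2, 0.2, 0.2])


def test_separated_boxes_no_contact():
    pos = np.array([[0.0, 0.0, 0.2], [3.0, 0.0, 0.2]])
    half = np.array([[0.6, 0.2, 0.2], [0.6, 0.2, 0.2]])
    nc, ca, cb, *_ = _contacts(pos, _identity_quats(2), half)
    assert not any(cb[:nc] >= 0)


def _ground_contacts_for(coms, halves):
    contacts = []
    for i, (c, h) in enumerate(zip(coms, halves)):
        for sx in (-1, 1):
            for sy in (-1, 1):
                p = np.array([c[0] + sx * h[0], c[1] + sy * h[1], 0.0])
                contacts.append((i, -1, p, np.array([0.0, 0.0, 1.0])))
    return contacts


def test_statics_single_box_upright_vs_tilted():
    coms = np.array([[0.0, 0.0, 0.2]])
    halves = [(0.6, 0.2, 0.2)]
    contacts = _ground_contacts_for(coms, halves)
    masses = np.array([0.2])
    down = np.array([0.0, 0.0, -9.8])
    assert equilibrium_feasible(coms, masses, contacts, down, mu=1.0)
    # 60 deg tilt exceeds the friction cone (mu = 1 holds at most 45 deg)
    th = np.deg2rad(60)
    tilted = 9.8 * np.array([np.sin(th), 0.0, -np.cos(th)])
    assert not equilibrium_feasible(coms, masses, contacts, tilted, mu=1.0)


def test_statics_overhang_torque_infeasible():
    # block whose COM lies outside its support patch cannot balance
    coms = np.array([[0.0, 0.0, 0.6]])
    masses = np.array([0.2])
    down = np.array([0.0, 0.0, -9.8])
    patch = [
        (0, -1, np.array([0.3, -0.2, 0.4]), np.array([0.0, 0.0, 1.0])),
        (0, -1, np.array([0.3, 0.2, 0.4]), np.array([0.0, 0.0, 1.0])),
        (0, -1, np.array([0.6, -0.2, 0.4]), np.array([0.0, 0.0, 1.0])),
        (0, -1, np.array([0.6, 0.2, 0.4]), np.array([0.0, 0.0, 1.0])),
    ]
    assert not equilibrium_feasible(coms, masses, patch, down, mu=1.0)
    # the same patch centered under the COM balances
    centered = [
        (0, -1, np.array([sx * 0.2, sy * 0.2, 0.4]), np.array([0.0, 0.0, 1.0]))
        for sx in (-1, 1)
        for sy in (-1, 1)
    ]
    assert equilibrium_feasible(coms, masses, centered, down, mu=1.0)


def test_world_sleeping_fast_path_is_exact():
    centers = np.array([[0.0, 0.0, 0.2], [0.1, 0.0, 0.6]])
    halves = np.array([[0.6, 0.2, 0.2], [0.6, 0.2, 0.2]])
    world = World(centers, halves, np.full(2, 0.2), np.array([0.0, 0.0, -9.8]), EngineParams())
    pos, _ = world.run(50)
    assert np.array_equal(pos[0], pos[-1])
    assert not world.awake.any()


def test_world_wakes_unsupported_body():
    centers = np.array([[0.0, 0.0, 2.0]])
    halves = np.array([[0.2, 0.2, 0.2]])
    world = World(centers, halves, np.full(1, 0.2), np.array([0.0, 0.0, -9.8]), EngineParams())
    world.step()
    assert world.awake[0]
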