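import numpy as np
import pytest

import parbsbm as pb
from parbsbm import mc


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def energy_model():
    return pb.EnergyModel()


@pytest.fixture(scope="session")
def circle_3kb():
    return pb.build_initial_circle(3000, 0.0)


def scrambled_chain(n_cylinders: int, seed: int, n_moves: int = 150,
                    self_avoiding: bool = True) -> pb.ChainConformation:
    """Random closed equilateral chain built from pure crankshaft geometry."""
    rng = np.random.default_rng(seed)
    mp = mc.MoveParams(max_span=max(2, n_cylinders // 3),
                       max_angle=np.pi / 2)
    em = pb.EnergyModel()
    conf = pb.build_initial_circle(30 * n_cylinders, 0.0)
    kept = 0
    while kept < n_moves:
        cand, _ = mc.propose_crankshaft(conf, mp, rng)
        if not self_avoiding or pb.check_self_avoidance(cand, em):
            conf = cand
            kept += 1
    return conf


def writhe_brute_force(vertices: np.ndarray, q: int = 40) -> float:
    """Discretized double Gauss integral — the independent writhe oracle.

    Each segment is split into ``q`` sub-segments and the double line
    integral (4π)⁻¹ ∮∮ (t₁×t₂)·(r₁−r₂)/|r₁−r₂|³ ds₁ ds₂ is evaluated by the
    midpoint rule, skipping same-segment and adjacent-segment pairs (both
    contribute exactly zero for straight segments).
    """
    v = np.asarray(vertices, float)
    n = len(v)
    seg = np.roll(v, -1, axis=0) - v
    lens = np.linalg.norm(seg, axis=1)
    frac = (np.arange(q) + 0.5) / q
    pts = (v[:, None, :] + seg[:, None, :] * frac[None, :, None]).reshape(-1, 3)
    t = np.repeat(seg / lens[:, None], q, axis=0)
    ds = np.repeat(lens / q, q)
    seg_id = np.repeat(np.arange(n), q)
    diff = pts[:, None, :] - pts[None, :, :]
    num = np.einsum("ijk,ijk->ij", np.cross(t[:, None, :], t[None, :, :]), diff)
    d = np.linalg.norm(diff, axis=2)
    dd = (seg_id[:, None] - seg_id[None, :]) % n
    adj = (dd == 0) | (dd == 1) | (dd == n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.where(adj, 0.0, num / d ** 3)
    return float((integrand * ds[:, None] * ds[None, :]).sum() / (4 * np.pi))
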