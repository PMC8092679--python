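"""Geometry, topology and energetics of the self-avoiding rod-like chain.

Circular DNA is discretized into ``N`` rigid cylinders of length
``l = 10.2 nm`` (30 bp of B-DNA) articulated at their shared vertices.  The
chain carries a conserved linking number ``Lk``; its deviation from the
relaxed value ``Lk0`` defines the supercoiling density
``σ = (Lk − Lk0)/Lk0`` and is partitioned between writhe ``Wr`` (computed
from the 3-D geometry through the Gauss integral) and a uniform twist
deficit ``ΔTw = (Lk − Lk0) − Wr``.

Units: lengths in nm, energies in k_BT, topology in turns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from . import _kernels

BP_PER_CYLINDER = 30
CYLINDER_LENGTH_NM = 10.2
#: helical repeat (bp/turn) giving Lk0 = 2850 for a 30 kb circle
DEFAULT_HELICAL_REPEAT = 30000.0 / 2850.0

SIGMA_FLOOR = -0.08  # model untested below this supercoiling density

__all__ = [
    "ChainConformation",
    "EnergyModel",
    "TopologyState",
    "build_initial_circle",
    "bending_energy",
    "torsional_energy",
    "writhe",
    "check_self_avoidance",
    "radius_of_gyration",
    "mirror",
    "sample_joint_angles",
    "persistence_length_estimate",
]


def _langevin(k: float) -> float:
    return 1.0 / math.tanh(k) - 1.0 / k


def kappa_from_persistence(l_p: float, l: float, mapping: str = "discrete-wlc") -> float:
    """Per-joint bending constant κ (k_BT) reproducing persistence length l_p.

    ``discrete-wlc`` solves ⟨cos θ⟩ = coth κ − 1/κ = exp(−l/l_p), the exact
    mapping for a discrete worm-like chain at segment length ``l``;
    ``ratio`` is the naive continuum limit κ = l_p/l.
    """
    if mapping == "ratio":
        return l_p / l
    if mapping != "discrete-wlc":
        raise ValueError(f"unknown bending mapping {mapping!r}")
    target = math.exp(-l / l_p)
    return brentq(lambda k: _langevin(k) - target, 1e-6, 1e4, xtol=1e-12)


@dataclass(frozen=True)
class EnergyModel:
    """Elastic parameters of the rod-like chain (B-DNA defaults)."""

    persistence_length: float = 50.0   # nm
    torsional_stiffness: float = 86.0  # nm
    cylinder_length: float = CYLINDER_LENGTH_NM  # nm
    hardcore_radius: float = 2.0       # nm (effective electrostatic radius)
    bending_mapping: str = "discrete-wlc"

    def __post_init__(self) -> None:
        for name in ("persistence_length", "torsional_stiffness",
                     "cylinder_length", "hardcore_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kappa(self) -> float:
        """Per-joint bending constant (k_BT)."""
        return kappa_from_persistence(self.persistence_length,
                                      self.cylinder_length,
                                      self.bending_mapping)

    @property
    def min_distance(self) -> float:
        """Hard-core center-line distance between non-adjacent cylinders."""
        return 2.0 * self.hardcore_radius


@dataclass
class ChainConformation:
    """Closed chain of rigid cylinders plus its linking-number state.

    ``vertices[k]`` and ``vertices[(k+1) % N]`` bound cylinder ``k``; the
    chain closes from the last vertex back to the first.
    """

    vertices: np.ndarray           # (N, 3) nm
    linking_number: float          # Lk, turns
    relaxed_linking_number: float  # Lk0, turns
    cylinder_length: float = CYLINDER_LENGTH_NM

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")

    @property
    def n_cylinders(self) -> int:
        return self.vertices.shape[0]

    @property
    def sigma(self) -> float:
        return (self.linking_number - self.relaxed_linking_number) \
            / self.relaxed_linking_number

    @property
    def n_bp(self) -> int:
        return self.n_cylinders * BP_PER_CYLINDER

    def segment_lengths(self) -> np.ndarray:
        d = np.roll(self.vertices, -1, axis=0) - self.vertices
        return np.linalg.norm(d, axis=1)

    def copy(self) -> "ChainConformation":
        return replace(self, vertices=self.vertices.copy())

    def validate(self, em: Optional[EnergyModel] = None,
                 rtol: float = 1e-9) -> None:
        """Raise if segment lengths or the hard core are violated."""
        lens = self.segment_lengths()
        if not np.allclose(lens, self.cylinder_length, rtol=rtol, atol=0):
            raise ValueError("segment lengths deviate from the cylinder length")
        min_d = em.min_distance if em is not None else 4.0
        d = _kernels.min_nonadjacent_dist(self.vertices)
        if d < min_d * (1.0 - rtol):
            raise ValueError(
                f"non-adjacent cylinders at {d:.3f} nm < hard core {min_d} nm")


@dataclass(frozen=True)
class TopologyState:
    """Writhe/twist bookkeeping of a conformation: Lk − Lk0 = ΔTw + Wr."""

    writhe: float        # turns
    twist_deficit: float  # ΔTw = (Lk − Lk0) − Wr, turns
    sigma: float

    @classmethod
    def from_conformation(cls, conf: ChainConformation,
                          wr: Optional[float] = None) -> "TopologyState":
        if wr is None:
            wr = writhe(conf)
        d_lk = conf.linking_number - conf.relaxed_linking_number
        return cls(writhe=wr, twist_deficit=d_lk - wr, sigma=conf.sigma)


def build_initial_circle(n_bp: int, sigma: float,
                         helical_repeat: float = DEFAULT_HELICAL_REPEAT,
                         lk0: Optional[float] = None) -> ChainConformation:
    """Planar circular conformation of an ``n_bp`` plasmid at density σ.

    The circle of ``N = n_bp/30`` cylinders has Wr = 0, so the whole
    supercoiling deficit initially sits in twist.  ``Lk0`` defaults to
    ``round(n_bp / helical_repeat)``; the default repeat gives Lk0 = 2850
    at 30 kb.
    """
    if n_bp % BP_PER_CYLINDER != 0:
        raise ValueError(
            f"n_bp = {n_bp} is not a multiple of {BP_PER_CYLINDER} bp")
    if not (SIGMA_FLOOR <= sigma <= 0.0):
        warnings.warn(
            f"sigma = {sigma} outside [{SIGMA_FLOOR}, 0]: untested regime",
            stacklevel=2)
    n = n_bp // BP_PER_CYLINDER
    if lk0 is None:
        lk0 = float(round(n_bp / helical_repeat))
    radius = n * CYLINDER_LENGTH_NM / (2.0 * math.pi)
    # vertices of a regular N-gon; side length adjusted to exactly l
    theta = 2.0 * math.pi * np.arange(n) / n
    side = 2.0 * radius * math.sin(math.pi / n)
    scale = CYLINDER_LENGTH_NM / side
    r = radius * scale
    verts = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                             np.zeros(n)])
    return ChainConformation(vertices=verts,
                             linking_number=lk0 * (1.0 + sigma),
                             relaxed_linking_number=lk0)


def bending_energy(conf: ChainConformation, em: EnergyModel) -> float:
    """Total bending energy κ Σ_joints (1 − cos θ_i), in k_BT."""
    t = np.roll(conf.vertices, -1, axis=0) - conf.vertices
    t /= np.linalg.norm(t, axis=1)[:, None]
    cos_theta = np.einsum("ij,ij->i", t, np.roll(t, -1, axis=0))
    return em.kappa * float(np.sum(1.0 - cos_theta))


def writhe(conf) -> float:
    """Writhe (turns) of a closed polygon via the Gauss-integral closed form.

    Accepts a :class:`ChainConformation` or a bare (N, 3) vertex array.
    """
    v = conf.vertices if isinstance(conf, ChainConformation) else \
        np.ascontiguousarray(conf, dtype=np.float64)
    d = np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)
    if np.any(d < 1e-12):
        raise ValueError("chain has coincident consecutive vertices")
    return float(_kernels.writhe_full(v))


def torsional_energy(conf: ChainConformation, em: EnergyModel,
                     wr: Optional[float] = None) -> float:
    """Uniform-twist torsional energy E_tw = (2π²C/L)·ΔTw², in k_BT.

    The chain has no intrinsic curvature, so at fixed writhe the quadratic
    torsional energy is minimized by a homogeneous twist; ``ΔTw`` is the
    twist deficit (Lk − Lk0) − Wr in turns.
    """
    if wr is None:
        wr = writhe(conf)
    length = conf.n_cylinders * conf.cylinder_length
    d_tw = (conf.linking_number - conf.relaxed_linking_number) - wr
    return 2.0 * math.pi ** 2 * em.torsional_stiffness / length * d_tw ** 2


def check_self_avoidance(conf: ChainConformation,
                         em: Optional[EnergyModel] = None,
                         moved_range: Optional[tuple] = None) -> bool:
    """True iff non-adjacent cylinders keep center-line distance ≥ 2 r_e.

    ``moved_range = (start, stop)`` restricts the check to segments in the
    half-open periodic index interval against all others.
    """
    min_d = (em.min_distance if em is not None else 4.0)
    v = conf.vertices
    n = conf.n_cylinders
    if moved_range is None:
        return bool(_kernels.min_nonadjacent_dist(v) >= min_d)
    start, stop = moved_range
    moved = [(start + k) % n for k in range((stop - start) % n or n)]
    moved_set = set(moved)
    md2 = min_d * min_d
    for s in moved:
        s2 = (s + 1) % n
        for t in range(n):
            if t in moved_set:
                continue
            if (s - t) % n in (0, 1, n - 1):
                continue
            t2 = (t + 1) % n
            d2 = _kernels.segment_min_dist2(
                v[s, 0], v[s, 1], v[s, 2], v[s2, 0], v[s2, 1], v[s2, 2],
                v[t, 0], v[t, 1], v[t, 2], v[t2, 0], v[t2, 1], v[t2, 2])
            if d2 < md2:
                return False
    return True


def radius_of_gyration(conf) -> float:
    """Root-mean-square vertex distance from the centroid, in nm."""
    v = conf.vertices if isinstance(conf, ChainConformation) else np.asarray(conf)
    c = v.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((v - c) ** 2, axis=1))))


def mirror(conf: ChainConformation) -> ChainConformation:
    """Mirror image (z → −z); writhe changes sign under this reflection."""
    v = conf.vertices.copy()
    v[:, 2] *= -1.0
    return replace(conf, vertices=v)


def sample_joint_angles(em: EnergyModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Equilibrium joint angles θ of a torsion-free phantom open chain.

    For an open chain without excluded volume the joints are independent
    with density ∝ sin θ · exp(−κ(1 − cos θ)); ``cos θ`` is drawn exactly by
    inverse-CDF sampling of ∝ exp(κ u) on [−1, 1].
    """
    k = em.kappa
    u = rng.random(n)
    # cos θ = log(e^{−κ} + u (e^{κ} − e^{−κ})) / κ, computed stably
    cos_t = 1.0 + np.log1p((u - 1.0) * (1.0 - np.exp(-2.0 * k))) / k
    return np.arccos(np.clip(cos_t, -1.0, 1.0))


def persistence_length_estimate(angles: np.ndarray, l: float = CYLINDER_LENGTH_NM) -> float:
    """Persistence length −l / ln⟨cos θ⟩ from sampled joint angles."""
    return -l / math.log(float(np.mean(np.cos(angles))))
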