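"""Metropolis Monte-Carlo engine: crankshaft moves and the annealing protocol.

The chain is deformed by crankshaft rotations (a block of at most ``M``
consecutive cylinders rigidly rotated about the chord joining its end
vertices) accepted with Metropolis probability ``min(1, exp(−ΔE))``, where
ΔE collects the bending change at the two hinge joints and the torsional
change through the writhe.  Hard-core overlaps are rejected outright, which
together with chain closure conserves the linking number; a move whose
writhe jumps by more than one turn is also rejected as a strand-passage
signature.

Supercoiling is imposed by a simulated-annealing schedule: starting from a
relaxed circle, helices are removed stepwise (Δσ ≈ −0.005 per level for the
30 kb reference chain) and the chain relaxes at constant σ between steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .ensemble import ConformationEnsemble, Frame
from .polymer import (ChainConformation, EnergyModel, SIGMA_FLOOR,
                      bending_energy, build_initial_circle, writhe)

__all__ = [
    "MoveParams",
    "AnnealingSchedule",
    "SamplingPlan",
    "Trajectory",
    "propose_crankshaft",
    "metropolis_accept",
    "run_sweeps",
    "remove_helices",
    "run_annealing_protocol",
    "protocol_step_count",
]

#: sweeps-per-level of the quickest protocol; defines the rate unit v = 1
RATE_UNIT_SWEEPS = 5e5


@dataclass(frozen=True)
class MoveParams:
    """Crankshaft proposal parameters."""

    max_span: int = 100          # M, maximum rotated cylinders
    max_angle: float = math.pi / 4.0  # radians
    writhe_recompute_every: int = 1000  # accepted moves between full Wr refresh
    max_writhe_jump: float = 1.0  # turns; strand-passage guard

    def __post_init__(self) -> None:
        if self.max_span < 1:
            raise ValueError("max_span must be >= 1")
        if not (0.0 < self.max_angle <= math.pi):
            raise ValueError("max_angle must be in (0, pi]")


@dataclass(frozen=True)
class AnnealingSchedule:
    """Stepwise supercoiling schedule from σ = 0 down to σ_min."""

    sweeps_per_level: int
    helices_removed_per_step: float = 14.0
    sigma_values: Tuple[float, ...] = tuple(
        round(-0.005 * k, 5) for k in range(17))

    @property
    def n_levels(self) -> int:
        return len(self.sigma_values)

    @property
    def rate(self) -> float:
        """Normalized supercoiling rate v (v = 1 at 5×10⁵ sweeps/level)."""
        return RATE_UNIT_SWEEPS / self.sweeps_per_level

    @classmethod
    def for_chain(cls, lk0: float, sweeps_per_level: int,
                  sigma_min: float = -0.08, sigma_step: float = 0.005,
                  ) -> "AnnealingSchedule":
        """Schedule whose per-step helix removal tracks the σ grid for any Lk0.

        For the 30 kb reference chain (Lk0 = 2850) the removal rounds to the
        canonical 14 helices per step.
        """
        n_levels = int(round(-sigma_min / sigma_step)) + 1
        k = sigma_step * lk0
        if lk0 >= 1000:
            k = float(round(k))
        return cls(sweeps_per_level=sweeps_per_level,
                   helices_removed_per_step=k,
                   sigma_values=tuple(round(-sigma_step * i, 5)
                                      for i in range(n_levels)))


@dataclass(frozen=True)
class SamplingPlan:
    """How many runs to launch and which sweeps to store per σ level.

    Frames are drawn evenly from the second half of each level's sweeps,
    the first half serving as implicit re-equilibration after the helix
    removal.
    """

    n_runs: int = 20
    frames_per_run: int = 2500

    def frame_sweeps(self, n_sweeps: int) -> np.ndarray:
        lo = n_sweeps // 2
        return np.unique(np.linspace(lo, n_sweeps,
                                     self.frames_per_run).astype(np.int64))


@dataclass
class Trajectory:
    """Records of one constant-σ window: writhe per sweep, final energies."""

    sweeps: np.ndarray
    writhe: np.ndarray
    bending_energy: np.ndarray
    torsional_energy: np.ndarray
    acceptance_rate: float
    frames: List[Tuple[int, np.ndarray]] = field(default_factory=list)
    n_moves: int = 0


def propose_crankshaft(conf: ChainConformation, mp: MoveParams,
                       rng: np.random.Generator,
                       ) -> Tuple[ChainConformation, Tuple[int, int]]:
    """Propose one crankshaft rotation; returns (new conformation, (i, j)).

    Vertex ``i`` is uniform over the chain, the span ``j − i`` (mod N)
    uniform over ``1..M``; vertices strictly between ``i`` and ``j`` rotate
    rigidly about the i–j axis by an angle uniform in ±max_angle.  The
    proposal is symmetric, so no Hastings correction is needed.
    """
    n = conf.n_cylinders
    i = int(rng.integers(n))
    span = int(rng.integers(1, min(mp.max_span, n - 1) + 1))
    j = (i + span) % n
    angle = (2.0 * rng.random() - 1.0) * mp.max_angle
    new = conf.copy()
    if span > 1:
        v = new.vertices
        axis = v[j] - v[i]
        axis = axis / np.linalg.norm(axis)
        idx = (i + 1 + np.arange(span - 1)) % n
        p = v[idx] - v[i]
        ca, sa = math.cos(angle), math.sin(angle)
        v[idx] = (v[i] + p * ca + np.cross(np.broadcast_to(axis, p.shape), p) * sa
                  + np.outer(p @ axis, axis) * (1.0 - ca))
    return new, (i, j)


def metropolis_accept(delta_e: float, overlap: bool,
                      rng: np.random.Generator) -> bool:
    """Metropolis rule: never through the hard core, else min(1, e^{−ΔE})."""
    if overlap:
        return False
    if delta_e <= 0.0:
        return True
    return bool(rng.random() < math.exp(-delta_e))


def _torsion_prefactor(conf: ChainConformation, em: EnergyModel) -> float:
    length = conf.n_cylinders * conf.cylinder_length
    return 2.0 * math.pi ** 2 * em.torsional_stiffness / length


def run_sweeps(conf: ChainConformation, em: EnergyModel, mp: MoveParams,
               n_sweeps: int, rng: np.random.Generator,
               record_sweeps: Optional[Sequence[int]] = None,
               check_overlap: bool = True,
               torsion: bool = True,
               wr: Optional[float] = None) -> Trajectory:
    """Run ``n_sweeps`` sweeps at constant σ, mutating ``conf`` in place.

    A sweep is ``N/M`` elementary crankshaft attempts.  Writhe is updated
    incrementally from the moved-vs-static segment pairs and refreshed from
    scratch every ``mp.writhe_recompute_every`` accepted moves (drift beyond
    1e-6 turns triggers a warning).  Conformations are snapshotted at the
    sweep indices in ``record_sweeps``.
    """
    n = conf.n_cylinders
    moves_per_sweep = max(1, n // mp.max_span)
    kappa = em.kappa
    c_tw = _torsion_prefactor(conf, em) if torsion else 0.0
    d_lk = conf.linking_number - conf.relaxed_linking_number
    if wr is None:
        wr = writhe(conf)
    record = set(int(s) for s in record_sweeps) if record_sweeps is not None else set()

    v = conf.vertices
    min_dist2 = em.min_distance ** 2
    sweeps_idx, wr_series, eb_series, et_series = [], [], [], []
    frames: List[Tuple[int, np.ndarray]] = []
    n_acc = 0
    acc_since_refresh = 0
    n_moves = 0
    for sweep in range(1, n_sweeps + 1):
        rand = rng.random((moves_per_sweep, 4))
        wr, acc = _kernels.run_moves(
            v, kappa, c_tw, d_lk, wr, rand, min(mp.max_span, n - 1),
            mp.max_angle, min_dist2, mp.max_writhe_jump, check_overlap)
        n_acc += acc
        acc_since_refresh += acc
        n_moves += moves_per_sweep
        if acc_since_refresh >= mp.writhe_recompute_every:
            exact = float(_kernels.writhe_full(v))
            if abs(exact - wr) > 1e-6:
                warnings.warn(f"incremental writhe drift {exact - wr:.2e} "
                              "turns corrected", stacklevel=2)
            wr = exact
            acc_since_refresh = 0
        if math.isnan(wr):
            raise FloatingPointError("writhe became NaN; aborting run")
        sweeps_idx.append(sweep)
        wr_series.append(wr)
        if sweep in record:
            frames.append((sweep, v.copy()))
    eb = bending_energy(conf, em)
    d_tw = d_lk - wr
    traj = Trajectory(
        sweeps=np.array(sweeps_idx, dtype=np.int64),
        writhe=np.array(wr_series),
        bending_energy=np.array([eb]),
        torsional_energy=np.array([c_tw * d_tw ** 2]),
        acceptance_rate=n_acc / max(1, n_moves),
        frames=frames,
        n_moves=n_moves)
    return traj


def remove_helices(conf: ChainConformation, k: float) -> ChainConformation:
    """Decrement Lk by ``k`` turns (geometry untouched): Δσ = −k/Lk0."""
    if k < 0:
        raise ValueError("k must be >= 0")
    out = replace(conf, vertices=conf.vertices,
                  linking_number=conf.linking_number - k)
    if out.sigma < SIGMA_FLOOR - 1e-12:
        warnings.warn(f"sigma = {out.sigma:.4f} below the tested floor "
                      f"{SIGMA_FLOOR}", stacklevel=2)
    return out


def protocol_step_count(schedule: AnnealingSchedule, n_cylinders: int,
                        mp: MoveParams) -> int:
    """Total elementary MC steps of one annealing run (all σ levels)."""
    moves_per_sweep = max(1, n_cylinders // mp.max_span)
    return schedule.n_levels * schedule.sweeps_per_level * moves_per_sweep


def run_annealing_protocol(schedule: AnnealingSchedule, plan: SamplingPlan,
                           em: EnergyModel, mp: MoveParams,
                           n_bp: int = 30000, seed: int = 0,
                           lk0: Optional[float] = None,
                           check_overlap: bool = True,
                           ) -> ConformationEnsemble:
    """Full annealing protocol over ``plan.n_runs`` independent runs.

    Each run starts from the relaxed circle, relaxes ``sweeps_per_level``
    sweeps at each σ level (frames stored from the second half), then
    removes ``helices_removed_per_step`` helices to reach the next level.
    Runs use independent child streams spawned from the master seed, so the
    whole protocol is reproducible bit-for-bit from ``seed``.
    """
    ens = ConformationEnsemble(seed=seed)
    streams = np.random.SeedSequence(seed).spawn(plan.n_runs)
    for run_id, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        conf = build_initial_circle(n_bp, 0.0, lk0=lk0)
        wr = writhe(conf)
        for level, _sigma_nominal in enumerate(schedule.sigma_values):
            frame_sweeps = plan.frame_sweeps(schedule.sweeps_per_level)
            traj = run_sweeps(conf, em, mp, schedule.sweeps_per_level, rng,
                              record_sweeps=frame_sweeps,
                              check_overlap=check_overlap, wr=wr)
            wr = float(traj.writhe[-1])
            sig = conf.sigma
            for sweep, verts in traj.frames:
                ens.add(sig, Frame(run=run_id, sweep=sweep, vertices=verts,
                                   linking_number=conf.linking_number,
                                   relaxed_linking_number=conf.relaxed_linking_number,
                                   writhe=float(traj.writhe[sweep - 1])))
            if level < schedule.n_levels - 1:
                conf = remove_helices(conf, schedule.helices_removed_per_step)
    return ens
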