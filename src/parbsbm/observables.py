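"""Ensemble analyses: distance distributions, gyration, plectoneme branches.

Branch counting follows the local-writhe route: for every site the writhe
restricted to a ±m/2 window is computed with the same segment-pair Gauss
formula as the global writhe; plectonemic branch apexes show up as deep
local minima of that profile, separated from the background by a per-σ
threshold wr* placed at the antimode of the pooled minima distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from . import _kernels
from .ensemble import ConformationEnsemble, DistanceSamples
from .polymer import BP_PER_CYLINDER, ChainConformation, radius_of_gyration

__all__ = [
    "LocalWritheProfile",
    "BranchCallResult",
    "estimate_Ps",
    "local_writhe",
    "find_local_minima",
    "select_writhe_threshold",
    "branch_count",
    "branch_count_curve",
    "gyration_curve",
]


@dataclass
class LocalWritheProfile:
    """Windowed writhe wr(i) per site of one conformation (periodic)."""

    values: np.ndarray
    window: int = 10

    def __post_init__(self) -> None:
        if self.window % 2 != 0:
            raise ValueError("window m must be even")


@dataclass
class BranchCallResult:
    """Branch counts per conformation at a given σ, with the threshold used."""

    threshold: Optional[float]
    counts: np.ndarray              # per-frame branch counts
    minima_pooled: np.ndarray       # pooled local-minima values
    runs: np.ndarray                # run id per frame

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts)) if self.counts.size else 0.0


def _run_sem(values: np.ndarray, runs: np.ndarray) -> float:
    """Standard error of the mean across runs: sqrt(var(run means)/(n−1))."""
    uruns = np.unique(runs)
    if uruns.size < 2:
        return float("nan")
    means = np.array([values[runs == r].mean() for r in uruns])
    return float(np.sqrt(np.var(means) / (uruns.size - 1)))


def estimate_Ps(ensemble: ConformationEnsemble, sigma: float,
                s_grid: Sequence[int],
                r_bins: Optional[np.ndarray] = None,
                parS_vertex: Optional[int] = None,
                ) -> Tuple[Dict[int, Tuple[np.ndarray, np.ndarray]], DistanceSamples]:
    """Distance statistics P_s(r) of loci at genomic offsets s from parS.

    With ``parS_vertex=None`` the chain is treated as homogeneous and
    distances are pooled over every reference vertex and both genomic
    directions, which leaves the expectation unchanged while sharpening the
    estimate.  Offsets beyond half the circle are folded back (circular
    genome).  Returns per-s histograms normalized to ∫P dr = 1 plus the raw
    samples.
    """
    frames = ensemble.frames_at(sigma)
    if not frames:
        raise ValueError(f"no frames at sigma = {sigma}")
    n = frames[0].vertices.shape[0]
    half_bp = n * BP_PER_CYLINDER // 2
    samples: Dict[int, List[np.ndarray]] = {}
    for s in s_grid:
        s = int(s)
        if s % BP_PER_CYLINDER != 0:
            raise ValueError(f"s = {s} bp is not on the {BP_PER_CYLINDER} bp grid")
        s_eff = s % (n * BP_PER_CYLINDER)
        if s_eff > half_bp:
            warnings.warn(f"s = {s} bp beyond half the circle; folded",
                          stacklevel=2)
            s_eff = n * BP_PER_CYLINDER - s_eff
        k = s_eff // BP_PER_CYLINDER
        per_frame = []
        for fr in frames:
            v = fr.vertices
            if parS_vertex is None:
                d = np.linalg.norm(np.roll(v, -k, axis=0) - v, axis=1)
            else:
                i = parS_vertex
                d = np.linalg.norm(
                    v[[(i + k) % n, (i - k) % n]] - v[i], axis=1)
            per_frame.append(d)
        samples.setdefault(s, []).extend(per_frame)
    ds = DistanceSamples(
        samples={s: np.concatenate(a) for s, a in samples.items()},
        sigma=sigma)
    hists: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    if r_bins is not None:
        for s, r in ds.samples.items():
            h, edges = np.histogram(r, bins=r_bins, density=True)
            hists[s] = (h, edges)
    return hists, ds


def local_writhe(conf, m: int = 10) -> LocalWritheProfile:
    """Windowed writhe profile; m = 10 cylinders spans ≈ 2 persistence lengths."""
    v = conf.vertices if isinstance(conf, ChainConformation) else \
        np.ascontiguousarray(conf, dtype=np.float64)
    if m > v.shape[0]:
        raise ValueError("window m cannot exceed the chain length")
    if m % 2 != 0:
        raise ValueError("window m must be even")
    return LocalWritheProfile(values=_kernels.local_writhe_profile(v, m),
                              window=m)


def find_local_minima(profile) -> Tuple[np.ndarray, np.ndarray]:
    """Strict periodic local minima; plateaus collapse to their center.

    Returns ``(values, indices)``.  A constant profile has no minima.
    """
    w = profile.values if isinstance(profile, LocalWritheProfile) else \
        np.asarray(profile, dtype=float)
    n = w.size
    # start at a plateau boundary so a plateau wrapping index 0 stays whole
    start = next((k for k in range(n) if w[k] != w[k - 1]), None)
    if start is None:
        return np.array([]), np.array([], dtype=int)  # constant profile
    vals, idxs = [], []
    off = 0
    while off < n:
        i = (start + off) % n
        j_off = off
        while j_off + 1 < n and w[(start + j_off + 1) % n] == w[i]:
            j_off += 1
        left = w[(i - 1) % n]
        right = w[(start + j_off + 1) % n]
        if w[i] < left and w[i] < right:
            vals.append(w[i])
            idxs.append((start + off + (j_off - off) // 2) % n)
        off = j_off + 1
    order = np.argsort(idxs)
    return np.array(vals)[order], np.array(idxs, dtype=int)[order]


def select_writhe_threshold(pooled_minima: np.ndarray,
                            min_count: int = 100,
                            bandwidth=None,
                            grid_size: int = 512,
                            min_mode_mass: float = 0.01) -> Optional[float]:
    """Antimode threshold wr* separating plectonemic from background minima.

    A Gaussian KDE (Silverman bandwidth unless overridden) is evaluated over
    the pooled minima.  Modes are detected on the log-density (the
    plectonemic mode may carry little mass next to the background peak near
    zero) with a factor-2 prominence requirement, and must carry at least
    ``min_mode_mass`` of the pooled minima within one bandwidth to rule out
    stray outliers.  When a negative, clearly separated plectonemic mode
    exists, wr* is the deepest valley of the density between it and the
    background mode; otherwise the distribution is deemed unimodal, no
    plectonemes are called, and the threshold is undefined.
    """
    x = np.asarray(pooled_minima, dtype=float)
    if x.size < min_count:
        warnings.warn(f"only {x.size} pooled minima (< {min_count}); "
                      "threshold undefined", stacklevel=2)
        return None
    if np.ptp(x) < 1e-12:
        return None
    kde = gaussian_kde(x, bw_method=bandwidth)
    bw_abs = kde.factor * x.std()
    grid = np.linspace(x.min(), x.max(), grid_size)
    d = kde(grid)
    peaks, _props = find_peaks(np.log(d + 1e-300), prominence=math.log(2.0))
    if peaks.size == 0:
        return None
    bg = peaks.max()  # background (non-plectonemic) mode, closest to zero
    cands = [p for p in peaks if grid[p] < min(grid[bg] - bw_abs, 0.0)]
    if not cands:
        return None
    # the plectonemic mode: the densest separated candidate
    lo = max(cands, key=lambda p: d[p])
    valley = np.arange(lo, bg + 1)
    wr_star = float(grid[valley[np.argmin(d[valley])]])
    if wr_star >= 0:
        return None  # branches carry negative local writhe by construction
    if float(np.mean(x <= wr_star)) < min_mode_mass:
        return None  # stray outliers, not a plectonemic population
    return wr_star


def branch_count(profile, wr_star: Optional[float]) -> int:
    """Number of plectonemic branches: local minima with wr ≤ wr*."""
    if wr_star is None:
        return 0
    vals, _ = find_local_minima(profile)
    return int(np.sum(vals <= wr_star))


def branch_calls(ensemble: ConformationEnsemble, sigma: float, m: int = 10,
                 wr_star: Optional[float] = "auto",
                 min_count: int = 100) -> BranchCallResult:
    """Local-writhe branch calling for every frame at one σ level."""
    frames = ensemble.frames_at(sigma)
    profiles = [local_writhe(f.vertices, m) for f in frames]
    minima = [find_local_minima(p)[0] for p in profiles]
    pooled = np.concatenate([v for v in minima if v.size]) if minima else \
        np.array([])
    if wr_star == "auto":
        wr_star = select_writhe_threshold(pooled, min_count=min_count)
    if wr_star is None:
        counts = np.zeros(len(frames), dtype=int)
    else:
        counts = np.array([int(np.sum(v <= wr_star)) for v in minima])
    return BranchCallResult(threshold=wr_star, counts=counts,
                            minima_pooled=pooled,
                            runs=np.array([f.run for f in frames]))


def branch_count_curve(ensemble: ConformationEnsemble, m: int = 10,
                       wr_star_overrides: Optional[Dict[float, float]] = None,
                       min_count: int = 100):
    """Mean plectonemic-branch count ± SEM (across runs) per σ level."""
    rows = []
    for sig in ensemble.sigmas():
        override = (wr_star_overrides or {}).get(round(sig, 6), "auto")
        res = branch_calls(ensemble, sig, m=m, wr_star=override,
                           min_count=min_count)
        rows.append((sig, res.mean, _run_sem(res.counts.astype(float),
                                             res.runs), res.threshold))
    dt = [("sigma", float), ("mean", float), ("sem", float),
          ("wr_star", float)]
    return np.array([(s, mn, se, np.nan if t is None else t)
                     for s, mn, se, t in rows], dtype=dt)


def gyration_curve(ensemble: ConformationEnsemble):
    """Mean radius of gyration ± SEM (across runs) per σ level."""
    rows = []
    for sig in ensemble.sigmas():
        frames = ensemble.frames_at(sig)
        rg = np.array([radius_of_gyration(f.vertices) for f in frames])
        runs = np.array([f.run for f in frames])
        rows.append((sig, float(rg.mean()), _run_sem(rg, runs)))
    return np.array(rows, dtype=[("sigma", float), ("mean", float),
                                 ("sem", float)])
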