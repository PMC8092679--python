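"""Coverage-profile ingestion, normalization, and (σ, ω) grid fitting.

Experimental input is a processed ChIP-seq coverage profile (position vs
read count) with positions expressed in bp relative to the edge of the
centromeric site.  Profiles are background-subtracted, clipped at zero and
scaled to a maximum of 1, which puts them on the same [0, 1] scale as the
modeled binding profile B(s); model and data are then compared by RMSD over
a fit window (1.5–9 kb by default) that excludes promoter/roadblock
distortions near the centromere and the noisy far tail.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ensemble import DistanceSamples
from .sbm import BindingProfile, ClusterModel, binding_profile

__all__ = [
    "CoverageProfile",
    "FitResult",
    "read_coverage",
    "normalize_profile",
    "fragment_center_assign",
    "rmsd",
    "grid_fit",
]

DEFAULT_WINDOW = (1500.0, 9000.0)  # bp


@dataclass
class CoverageProfile:
    """Sorted genomic positions (bp) with coverage values."""

    positions: np.ndarray
    values: np.ndarray
    fragment_size: Optional[float] = None  # bp, metadata
    normalized: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have the same shape")
        order = np.argsort(self.positions, kind="stable")
        self.positions = self.positions[order]
        self.values = self.values[order]

    def __len__(self) -> int:
        return self.positions.size


def _merge_duplicates(pos: np.ndarray, val: np.ndarray):
    upos, inv = np.unique(pos, return_inverse=True)
    uval = np.zeros_like(upos, dtype=float)
    np.add.at(uval, inv, val)
    return upos, uval


def read_coverage(path, fmt: Optional[str] = None) -> CoverageProfile:
    """Read a coverage profile from two-column TSV or 4-column bedGraph.

    TSV rows are point positions; bedGraph intervals (0-based half-open)
    are assigned to their center position.  Duplicate positions are merged
    by summing.
    """
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = "bedgraph" if ext in (".bedgraph", ".bg") else "tsv"
    if fmt not in ("tsv", "bedgraph"):
        raise ValueError(f"unknown format {fmt!r}")
    ncols = 4 if fmt == "bedgraph" else 2
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         usecols=range(ncols))
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty coverage file") from None
    if df.empty:
        raise ValueError(f"{path}: empty coverage file")
    if fmt == "tsv":
        for col in (0, 1):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"{path}: non-numeric value at line {int(bad.idxmax()) + 1}")
        pos = df[0].astype(float).to_numpy()
        val = df[1].astype(float).to_numpy()
    else:
        for col in (1, 2, 3):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"{path}: non-numeric value at line {int(bad.idxmax()) + 1}")
        start = df[1].astype(float).to_numpy()
        end = df[2].astype(float).to_numpy()
        order = np.argsort(start, kind="stable")
        if np.any(start[order][1:] < end[order][:-1]):
            raise ValueError(f"{path}: overlapping bedGraph intervals")
        pos = (start + end) / 2.0
        val = df[3].astype(float).to_numpy()
    pos, val = _merge_duplicates(pos, val)
    return CoverageProfile(positions=pos, values=val)


def normalize_profile(cp: CoverageProfile, background=0.0) -> CoverageProfile:
    """Background-subtract, clip at zero, and scale the maximum to 1.

    ``background`` is either a value or a ``(lo, hi)`` bp window whose mean
    coverage is used as the background estimate.
    """
    if isinstance(background, (tuple, list)):
        lo, hi = background
        mask = (cp.positions >= lo) & (cp.positions <= hi)
        if not mask.any():
            raise ValueError("background window contains no data points")
        background = float(cp.values[mask].mean())
    if background < 0:
        raise ValueError("background must be non-negative")
    v = np.clip(cp.values - background, 0.0, None)
    vmax = v.max() if v.size else 0.0
    if vmax <= 0:
        raise ValueError("profile is identically zero after background "
                         "subtraction")
    return replace(cp, values=v / vmax, normalized=True)


def fragment_center_assign(read_starts: Sequence[float],
                           fragment_size: float,
                           strands: Optional[Sequence[str]] = None,
                           ) -> CoverageProfile:
    """Count each read at the center of its DNA fragment.

    Plus-strand reads shift by +fragment_size/2, minus-strand reads by
    −fragment_size/2 (the 5' end faces the fragment either way).
    """
    if fragment_size <= 0:
        raise ValueError("fragment_size must be positive")
    starts = np.asarray(read_starts, dtype=float)
    if strands is None:
        shift = np.full(starts.shape, fragment_size / 2.0)
    else:
        sign = np.where(np.asarray(strands) == "-", -1.0, 1.0)
        shift = sign * fragment_size / 2.0
    centers = starts + shift
    pos, counts = np.unique(centers, return_counts=True)
    return CoverageProfile(positions=pos, values=counts.astype(float),
                           fragment_size=float(fragment_size))


def rmsd(model: BindingProfile, data: CoverageProfile,
         window: Tuple[float, float] = DEFAULT_WINDOW) -> float:
    """RMSD between model and data over the fit window.

    The model is linearly interpolated onto the data positions inside the
    window; no amplitude rescaling is applied (both curves live on [0, 1]).
    """
    lo, hi = window
    mask = (data.positions >= lo) & (data.positions <= hi)
    if mask.sum() < 10:
        raise ValueError(f"fewer than 10 data points in window [{lo}, {hi}]")
    pos = data.positions[mask]
    if model.s.min() > lo or model.s.max() < hi:
        raise ValueError("model does not cover the fit window")
    m = model.interp(pos)
    return float(np.sqrt(np.mean((m - data.values[mask]) ** 2)))


@dataclass
class FitResult:
    """RMSD landscape over the (σ, ω) grid and its minimizer."""

    sigmas: np.ndarray
    omegas: np.ndarray
    rmsd: np.ndarray  # (n_sigma, n_omega)
    best_sigma: float
    best_omega: float
    window: Tuple[float, float]
    ties: int = 0

    @property
    def best_rmsd(self) -> float:
        return float(self.rmsd.min())

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, w, self.rmsd[i, j])
                for i, s in enumerate(self.sigmas)
                for j, w in enumerate(self.omegas)]
        return pd.DataFrame(rows, columns=["sigma", "omega", "rmsd"])


def grid_fit(samples_by_sigma: Dict[float, DistanceSamples],
             kind: str,
             omega_grid: Iterable[float],
             data: CoverageProfile,
             window: Tuple[float, float] = DEFAULT_WINDOW,
             convolve_center: Optional[bool] = None) -> FitResult:
    """RMSD of the modeled B(s) against data for every (σ, ω) cell.

    Ties at the minimum are broken toward smaller ω, then larger |σ|; the
    number of tied cells is reported in the result.
    """
    sigmas = sorted(samples_by_sigma, reverse=True)
    omegas = sorted(float(w) for w in omega_grid)
    mat = np.empty((len(sigmas), len(omegas)))
    for i, sig in enumerate(sigmas):
        ds = samples_by_sigma[sig]
        for j, w in enumerate(omegas):
            cm = ClusterModel(kind=kind, omega=w,
                              convolve_center=convolve_center)
            prof = binding_profile(ds, cm)
            mat[i, j] = rmsd(prof, data, window)
    best = mat.min()
    tied = np.argwhere(mat <= best)
    ties = tied.shape[0]
    # smaller omega first, then larger |sigma| (sigmas sorted 0 → most negative)
    tied = sorted(map(tuple, tied), key=lambda ij: (omegas[ij[1]], -abs(sigmas[ij[0]])))
    bi, bj = tied[0]
    return FitResult(sigmas=np.array(sigmas), omegas=np.array(omegas),
                     rmsd=mat, best_sigma=float(sigmas[bi]),
                     best_omega=float(omegas[bj]), window=window, ties=ties)
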