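"""In-memory containers for sampled conformations and distance statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional

import numpy as np

__all__ = ["Frame", "ConformationEnsemble", "DistanceSamples"]


@dataclass
class Frame:
    """One stored conformation with its provenance."""

    run: int
    sweep: int
    vertices: np.ndarray  # (N, 3) nm
    linking_number: float
    relaxed_linking_number: float
    writhe: float


def sigma_key(sigma: float) -> float:
    """Canonical rounding of a supercoiling density used as a dict key."""
    return round(float(sigma), 6)


@dataclass
class ConformationEnsemble:
    """Per-σ collections of sampled conformations with run/sweep provenance."""

    frames: Dict[float, List[Frame]] = field(default_factory=dict)
    seed: Optional[int] = None

    def add(self, sigma: float, frame: Frame) -> None:
        self.frames.setdefault(sigma_key(sigma), []).append(frame)

    def sigmas(self) -> List[float]:
        """σ levels, from relaxed (0) to most supercoiled."""
        return sorted(self.frames, reverse=True)

    def frames_at(self, sigma: float) -> List[Frame]:
        return self.frames[sigma_key(sigma)]

    def vertices_at(self, sigma: float) -> List[np.ndarray]:
        return [f.vertices for f in self.frames_at(sigma)]

    def runs_at(self, sigma: float) -> List[int]:
        return sorted({f.run for f in self.frames_at(sigma)})

    def __len__(self) -> int:
        return sum(len(v) for v in self.frames.values())

    def __iter__(self) -> Iterator[Frame]:
        for sig in self.sigmas():
            yield from self.frames[sig]


@dataclass
class DistanceSamples:
    """Spatial distances r (nm) from a reference locus, per genomic offset s.

    ``samples[s]`` holds draws of the 3-D distance between a locus at
    genomic offset ``s`` (bp) from the reference vertex and the reference
    itself, pooled over frames (and over reference positions when the chain
    is treated as homogeneous).
    """

    samples: Dict[int, np.ndarray] = field(default_factory=dict)
    sigma: Optional[float] = None

    @property
    def s_grid(self) -> np.ndarray:
        return np.array(sorted(self.samples), dtype=float)

    def __getitem__(self, s: int) -> np.ndarray:
        return self.samples[int(s)]

    def n_samples(self) -> int:
        return sum(a.size for a in self.samples.values())
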