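"""Trajectory persistence (HDF5) and plain-text exporters.

HDF5 layout::

    /run_<k>/sigma_<v>/frame_<t>/vertices   (N, 3) float64, nm
        attrs: Lk, Lk0, Wr, sweep
    /  attrs: seed

Group names encode σ with 6 decimals (e.g. ``sigma_-0.040000``).
"""

from __future__ import annotations

from typing import Iterable, Optional

import h5py
import numpy as np

from .ensemble import ConformationEnsemble, Frame

__all__ = ["save_ensemble", "load_ensemble", "write_xyz"]


def _sigma_name(sigma: float) -> str:
    return f"sigma_{sigma:.6f}"


def save_ensemble(ens: ConformationEnsemble, path) -> None:
    with h5py.File(path, "w") as h5:
        if ens.seed is not None:
            h5.attrs["seed"] = ens.seed
        counters: dict = {}
        for sig in ens.sigmas():
            for fr in ens.frames_at(sig):
                key = (fr.run, sig)
                t = counters.get(key, 0)
                counters[key] = t + 1
                grp = h5.require_group(f"run_{fr.run}/{_sigma_name(sig)}")
                fgrp = grp.create_group(f"frame_{t}")
                fgrp.create_dataset("vertices", data=fr.vertices)
                fgrp.attrs["Lk"] = fr.linking_number
                fgrp.attrs["Lk0"] = fr.relaxed_linking_number
                fgrp.attrs["Wr"] = fr.writhe
                fgrp.attrs["sweep"] = fr.sweep


def load_ensemble(path) -> ConformationEnsemble:
    ens = ConformationEnsemble()
    with h5py.File(path, "r") as h5:
        if "seed" in h5.attrs:
            ens.seed = int(h5.attrs["seed"])
        for run_name in sorted(h5, key=lambda s: int(s.split("_")[1])):
            run_id = int(run_name.split("_")[1])
            for sig_name in h5[run_name]:
                sigma = float(sig_name.split("_", 1)[1])
                grp = h5[run_name][sig_name]
                for frame_name in sorted(grp, key=lambda s: int(s.split("_")[1])):
                    fgrp = grp[frame_name]
                    ens.add(sigma, Frame(
                        run=run_id,
                        sweep=int(fgrp.attrs["sweep"]),
                        vertices=np.asarray(fgrp["vertices"]),
                        linking_number=float(fgrp.attrs["Lk"]),
                        relaxed_linking_number=float(fgrp.attrs["Lk0"]),
                        writhe=float(fgrp.attrs["Wr"])))
    return ens


def write_xyz(frames: Iterable[np.ndarray], path,
              comment: str = "rod-like chain, coordinates in nm") -> None:
    """Plain-text XYZ export (one frame per block) for visualization."""
    with open(path, "w") as fh:
        for verts in frames:
            v = np.asarray(verts)
            fh.write(f"{v.shape[0]}\n{comment}\n")
            for x, y, z in v:
                fh.write(f"C {x:.4f} {y:.4f} {z:.4f}\n")
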