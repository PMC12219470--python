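"""File I/O for the standard interchange formats used by the CLI."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Footprint, TraceSet, Trajectory
from .crosstalk import SpectraSet

__all__ = [
    "write_trajectory_csv", "read_trajectory_csv",
    "write_traces_csv", "read_traces_csv",
    "write_footprints_h5", "read_footprints_h5",
    "read_spectra_csv", "load_spectra_set",
    "write_movie_tiff",
]


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"frame": np.arange(traj.n_frames),
                  "x_px": traj.x_px, "y_px": traj.y_px}).to_csv(path, index=False)


def read_trajectory_csv(
    path: str | Path, fps: float, track_length_cm: float, px_per_cm: float
) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(df["x_px"].to_numpy(), df["y_px"].to_numpy(),
                      fps=fps, track_length_cm=track_length_cm, px_per_cm=px_per_cm)


def write_traces_csv(traces: TraceSet, path: str | Path) -> None:
    df = pd.DataFrame(traces.values)
    df.index.name = "cell"
    df.to_csv(path, float_format="%.8g")


def read_traces_csv(path: str | Path, kind: str, fps: float) -> TraceSet:
    df = pd.read_csv(path, index_col=0)
    return TraceSet(df.to_numpy(), kind, fps)


def write_footprints_h5(footprints: list[Footprint], path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        for fp in footprints:
            grp = fh.create_group(f"cell_{fp.cell_id}")
            grp.create_dataset("weights", data=fp.weights, compression="gzip")
            grp.attrs["centroid"] = fp.centroid
            grp.attrs["cell_id"] = fp.cell_id


def read_footprints_h5(path: str | Path) -> list[Footprint]:
    out = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh, key=lambda n: int(n.split("_")[1])):
            grp = fh[name]
            out.append(Footprint(
                cell_id=int(grp.attrs["cell_id"]),
                weights=grp["weights"][()],
                centroid=tuple(grp.attrs["centroid"]),
            ))
    return out


def read_spectra_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column CSV (wavelength_nm, value); header optional."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, value)")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    val = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(wl)
    return wl[order], val[order]


def load_spectra_set(
    emission_csv: str | Path, green_csv: str | Path, red_csv: str | Path
) -> SpectraSet:
    """Load three curves and interpolate onto the emission wavelength grid."""
    wl, em = read_spectra_csv(emission_csv)
    out = {"emission": em}
    for name, p in (("transmission_green", green_csv), ("transmission_red", red_csv)):
        twl, tv = read_spectra_csv(p)
        if tv.max() > 1.5:  # percent-scale transmission curves
            tv = tv / 100.0
        out[name] = np.clip(np.interp(wl, twl, tv, left=0.0, right=0.0), 0.0, 1.0)
    return SpectraSet(wavelengths=wl, **out)


def write_movie_tiff(movie: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))
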