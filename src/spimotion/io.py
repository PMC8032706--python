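"""File formats: grayscale images, S-matrices, measurements, trajectories.

Images are 8/16-bit PNG or TIFF, normalized to [0, 1] on load. S-matrices
persist as first row + (P, Q) header (HDF5 or CSV). Measurement series go
to HDF5 (single metadata-carrying file) with a CSV fallback; trajectories
to CSV with columns (index, dx, dy).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd

from .acquisition import ImageFrame, MeasurementSeries, MotionTrajectory, as_image
from .smatrix import CyclicSMatrix

__all__ = [
    "load_image",
    "save_image",
    "load_smatrix",
    "save_smatrix",
    "load_measurements",
    "save_measurements",
    "load_trajectory",
    "save_trajectory",
]


def load_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF, scaled to [0, 1] by its bit depth."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) to luma
        arr = arr[..., :3].mean(axis=-1)
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def save_image(path, U, bit_depth: int = 16) -> None:
    """Write an image as 8- or 16-bit grayscale PNG/TIFF, clipped to [0, 1]."""
    U = np.clip(as_image(U), 0.0, 1.0)
    if bit_depth == 16:
        iio.imwrite(path, (U * 65535.0 + 0.5).astype(np.uint16))
    elif bit_depth == 8:
        iio.imwrite(path, (U * 255.0 + 0.5).astype(np.uint8))
    else:
        raise ValueError("bit_depth must be 8 or 16")


def save_smatrix(path, S: CyclicSMatrix) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("first_row", data=S.first_row)
            f.attrs["P"] = S.P
            f.attrs["Q"] = S.Q
    else:  # CSV: header row P,Q then the first row values
        with open(path, "w") as f:
            f.write(f"# P={S.P} Q={S.Q}\n")
            f.write(",".join(map(str, S.first_row.tolist())) + "\n")


def load_smatrix(path) -> CyclicSMatrix:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            first_row = f["first_row"][...]
            P, Q = int(f.attrs["P"]), int(f.attrs["Q"])
    else:
        with open(path) as f:
            header = f.readline().strip().lstrip("#").split()
            kv = dict(tok.split("=") for tok in header)
            P, Q = int(kv["P"]), int(kv["Q"])
            first_row = np.array(f.readline().strip().split(","), dtype=np.int8)
    return CyclicSMatrix(first_row=first_row, P=P, Q=Q)


_META_FIELDS = ("K", "P", "Q", "noise_sigma")


def save_measurements(path, ms: MeasurementSeries, **extra_meta) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("b_tot", data=ms.b_tot)
            for k in _META_FIELDS:
                f.attrs[k] = getattr(ms, k)
            for k, v in extra_meta.items():
                f.attrs[k] = v
    else:
        df = pd.DataFrame({"index": np.arange(ms.b_tot.size), "b": ms.b_tot})
        with open(path, "w") as f:
            f.write(f"# K={ms.K} P={ms.P} Q={ms.Q} noise_sigma={ms.noise_sigma}\n")
            df.to_csv(f, index=False)


def load_measurements(path) -> MeasurementSeries:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for k in _META_FIELDS:
                if k not in f.attrs:
                    raise KeyError(f"measurement file missing metadata field {k!r}")
            return MeasurementSeries(
                b_tot=f["b_tot"][...],
                K=int(f.attrs["K"]),
                P=int(f.attrs["P"]),
                Q=int(f.attrs["Q"]),
                noise_sigma=float(f.attrs["noise_sigma"]),
            )
    with open(path) as f:
        header = f.readline().strip().lstrip("#").split()
        kv = dict(tok.split("=") for tok in header)
        for k in _META_FIELDS:
            if k not in kv:
                raise KeyError(f"measurement file missing metadata field {k!r}")
        df = pd.read_csv(f)
    return MeasurementSeries(
        b_tot=df["b"].to_numpy(),
        K=int(kv["K"]),
        P=int(kv["P"]),
        Q=int(kv["Q"]),
        noise_sigma=float(kv["noise_sigma"]),
    )


def save_trajectory(path, traj: MotionTrajectory) -> None:
    pd.DataFrame(
        {"index": np.arange(len(traj)), "dx": traj.dx, "dy": traj.dy}
    ).to_csv(path, index=False)


def load_trajectory(path) -> MotionTrajectory:
    df = pd.read_csv(path)
    return MotionTrajectory(dx=df["dx"].to_numpy(), dy=df["dy"].to_numpy())
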