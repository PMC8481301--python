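"""File formats: HDF5/CSV frame sequences, spirometry CSV, reconstruction
matrices, index tables, and YAML run configuration."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .greit import PixelGrid, ReconstructionMatrix
from .synthetic import EITFrameSequence, SpirometryTrace


def write_sequence_h5(seq: EITFrameSequence, path: str | Path) -> None:
    """Write a frame sequence to HDF5 (datasets ``frames``/``timestamps``,
    protocol metadata as root attributes)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("frames", data=seq.frames)
        fh.create_dataset("timestamps", data=seq.timestamps)
        fh.attrs["frame_rate"] = seq.frame_rate
        fh.attrs["device"] = seq.device
        fh.attrs["current_amplitude"] = seq.current_amplitude
        fh.attrs["frequency"] = seq.frequency
        if seq.seed is not None:
            fh.attrs["seed"] = seq.seed


def read_sequence_h5(path: str | Path) -> EITFrameSequence:
    with h5py.File(path, "r") as fh:
        return EITFrameSequence(
            frames=fh["frames"][()],
            timestamps=fh["timestamps"][()],
            frame_rate=float(fh.attrs["frame_rate"]),
            device=str(fh.attrs.get("device", "A")),
            seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
            current_amplitude=float(fh.attrs.get("current_amplitude", 5e-3)),
            frequency=float(fh.attrs.get("frequency", 1e5)),
        )


def write_sequence_csv(seq: EITFrameSequence, path: str | Path) -> None:
    """Flat CSV dialect: one frame per row, first column ``time_s``,
    remaining columns the measurement channels ``ch001``..."""
    n_ch = seq.frames.shape[1]
    df = pd.DataFrame(seq.frames,
                      columns=[f"ch{i + 1:03d}" for i in range(n_ch)])
    df.insert(0, "time_s", seq.timestamps)
    df.to_csv(path, index=False)


def read_sequence_csv(path: str | Path,
                      frame_rate: float | None = None,
                      device: str = "A") -> EITFrameSequence:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    frames = df.drop(columns=["time_s"]).to_numpy()
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return EITFrameSequence(frames=frames, timestamps=t,
                            frame_rate=frame_rate, device=device)


def write_spirometry_csv(trace: SpirometryTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.timestamps,
                  "volume_L": trace.volume}).to_csv(path, index=False)


def read_spirometry_csv(path: str | Path) -> SpirometryTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return SpirometryTrace(timestamps=t, volume=df["volume_L"].to_numpy(),
                           sampling_rate=rate)


def write_reconstruction_h5(R: ReconstructionMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("matrix", data=R.matrix)
        fh.create_dataset("mask", data=R.grid.mask)
        fh.create_dataset("pixel_centres", data=R.grid.centres)
        fh.attrs["grid_size"] = R.grid.size
        fh.attrs["semi_axes"] = R.grid.semi_axes
        fh.attrs["noise_level"] = R.noise_level
        fh.attrs["lambda"] = R.lam
        fh.attrs["noise_figure_target"] = R.noise_figure_target
        fh.attrs["noise_figure_achieved"] = R.noise_figure_achieved
        fh.attrs["n_targets"] = R.n_targets
        fh.attrs["target_radius"] = R.target_radius


def read_reconstruction_h5(path: str | Path) -> ReconstructionMatrix:
    with h5py.File(path, "r") as fh:
        grid = PixelGrid(
            size=int(fh.attrs["grid_size"]),
            mask=fh["mask"][()].astype(bool),
            centres=fh["pixel_centres"][()],
            semi_axes=tuple(fh.attrs["semi_axes"]),
        )
        return ReconstructionMatrix(
            matrix=fh["matrix"][()], grid=grid,
            noise_level=float(fh.attrs["noise_level"]),
            lam=float(fh.attrs["lambda"]),
            noise_figure_target=float(fh.attrs["noise_figure_target"]),
            noise_figure_achieved=float(fh.attrs["noise_figure_achieved"]),
            n_targets=int(fh.attrs["n_targets"]),
            target_radius=float(fh.attrs["target_radius"]),
        )


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (nested key-value mapping)."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping")
    return cfg
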