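"""Per-channel normalization and plain-text model-input files.

Real multi-sensor front ends have per-channel offsets and gain mismatches
(different microphone batches, component tolerances).  Before the spiking
network sees the data, each channel is normalized independently, in order:

1. subtract the channel mean;
2. divide by the channel standard deviation (population convention);
3. divide by the maximum absolute value, so every channel spans exactly
   +/- 1.

Step 3 makes the result invariant to the std convention in step 2, and the
whole procedure is invariant to any positive affine transform of the input
-- which is precisely what removes the front-end mismatch.  Normalization is
computed over the entire recording (offline post-processing), not per
window.

The per-leg text files (one sample per line) are the network's historical
input format; a small YAML sidecar makes the directory self-describing and
losslessly re-loadable at the written precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scenes import MultichannelRecording

__all__ = [
    "DegenerateChannelError",
    "normalize_channels",
    "export_leg_files",
    "read_leg_files",
]

_LEG_FORMAT = "%.6f"
_SIDECAR = "legs_meta.yaml"


class DegenerateChannelError(ValueError):
    """A channel has zero variance and cannot be normalized."""

    def __init__(self, channel: int):
        self.channel = channel
        super().__init__(f"channel {channel} has zero variance")


def normalize_channels(
    rec: MultichannelRecording,
) -> tuple[MultichannelRecording, pd.DataFrame]:
    """Normalize every channel to zero mean and max-abs exactly 1.

    Returns the normalized recording and a report with the pre-normalization
    max, mean and standard deviation of each channel.
    """
    chans = rec.channels
    means = chans.mean(axis=1)
    stds = chans.std(axis=1)  # population (divide by N)
    maxes = np.abs(chans).max(axis=1)
    for j, s in enumerate(stds):
        if s == 0.0:
            raise DegenerateChannelError(j)
    centered = (chans - means[:, None]) / stds[:, None]
    out = centered / np.abs(centered).max(axis=1)[:, None]
    report = pd.DataFrame(
        {"channel": np.arange(rec.n_channels), "max": maxes, "mean": means, "std": stds}
    )
    normalized = MultichannelRecording(
        fs=rec.fs,
        channels=out,
        geometry=rec.geometry,
        trajectory=rec.trajectory,
        meta={**rec.meta, "normalized": True},
    )
    return normalized, report


def export_leg_files(rec: MultichannelRecording, directory: str | Path) -> list[Path]:
    """Write one plain-text file per channel (leg_1.txt .. leg_N.txt).

    One fixed-decimal sample value per line, plus a YAML sidecar recording
    the sample rate, sample count and channel count.  Fails if the recording
    has a geometry with a different sensor count.
    """
    if rec.geometry is not None and rec.geometry.n_sensors != rec.n_channels:
        raise ValueError(
            f"recording has {rec.n_channels} channels but the geometry "
            f"declares {rec.geometry.n_sensors} sensors"
        )
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for j in range(rec.n_channels):
        p = directory / f"leg_{j + 1}.txt"
        np.savetxt(p, rec.channels[j], fmt=_LEG_FORMAT)
        paths.append(p)
    sidecar = {
        "fs": float(rec.fs),
        "n_samples": int(rec.n_samples),
        "n_channels": int(rec.n_channels),
        "format": "one sample per line, %.6f",
    }
    if rec.geometry is not None:
        sidecar["geometry"] = rec.geometry.to_dict()
    (directory / _SIDECAR).write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return paths


def read_leg_files(directory: str | Path) -> MultichannelRecording:
    """Inverse of :func:`export_leg_files` (lossless at the written precision)."""
    directory = Path(directory)
    meta = yaml.safe_load((directory / _SIDECAR).read_text())
    channels = [
        np.loadtxt(directory / f"leg_{j + 1}.txt")
        for j in range(int(meta["n_channels"]))
    ]
    geometry = None
    if "geometry" in meta:
        from .geometry import ArrayGeometry

        geometry = ArrayGeometry.from_dict(meta["geometry"])
    return MultichannelRecording(
        fs=float(meta["fs"]), channels=np.vstack(channels), geometry=geometry
    )
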