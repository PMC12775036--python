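"""The multichannel recording container and its plain-text serialization."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


@dataclass
class Recording:
    """A channels x samples EEG signal matrix in microvolts.

    ``retained`` is a per-sample boolean mask maintained by the cleaning
    steps; samples marked False have been rejected and are excluded from
    all spectral estimates downstream.
    """

    subject: str
    system: str
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} signal rows but "
                f"{len(self.channels)} channel labels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.retained is None:
            self.retained = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.retained = np.asarray(self.retained, dtype=bool)
            if self.retained.shape != (self.data.shape[1],):
                raise ValueError("retained mask length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def fraction_retained(self) -> float:
        return float(self.retained.mean()) if self.n_samples else 0.0

    def channel_index(self, channel: str) -> int:
        try:
            return list(self.channels).index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not present; available: {list(self.channels)}"
            ) from None

    def channel_data(self, channel: str, retained_only: bool = True) -> np.ndarray:
        x = self.data[self.channel_index(channel)]
        return x[self.retained] if retained_only else x

    def copy(self) -> "Recording":
        return replace(
            self, data=self.data.copy(), retained=self.retained.copy(),
            channels=tuple(self.channels),
        )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write one recording as a commented-header TSV (samples x channels)."""
    path = Path(path)
    header = (
        f"# subject\t{rec.subject}\n"
        f"# system\t{rec.system}\n"
        f"# fs_hz\t{rec.fs:.6g}\n"
        f"# channels\t{','.join(rec.channels)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, rec.data.T, fmt="%.6f", delimiter="\t")


def read_recording(path: str | Path) -> Recording:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("\t")
                meta[key] = value
            elif line.strip():
                rows.append([float(v) for v in line.split("\t")])
    data = np.asarray(rows).T
    return Recording(
        subject=meta["subject"],
        system=meta["system"],
        fs=float(meta["fs_hz"]),
        channels=tuple(meta["channels"].split(",")),
        data=data,
    )
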