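"""In-memory EEG recording container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import CHANNELS


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    data is channels x samples in microvolts; ``timestamps`` carry the
    session-clock time of every sample (wireless transport can drop
    packets, so timestamp deltas are not guaranteed to equal the nominal
    sampling period).
    """

    data: np.ndarray
    rate: float = 500.0
    channels: tuple[str, ...] = CHANNELS
    timestamps: np.ndarray | None = None
    participant: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be ({len(self.channels)}, n_samples), got {self.data.shape}"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.timestamps is None:
            self.timestamps = np.arange(self.data.shape[1]) / self.rate
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape[0] != self.data.shape[1]:
            raise ValueError("timestamps must match the number of samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def index_of(self, channel: str) -> int:
        return self.channels.index(channel)

    def copy_with(self, **kwargs) -> "EEGRecording":
        out = dict(
            data=self.data.copy(),
            rate=self.rate,
            channels=self.channels,
            timestamps=None if self.timestamps is None else self.timestamps.copy(),
            participant=self.participant,
        )
        out.update(kwargs)
        return EEGRecording(**out)
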