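"""In-memory container for a multichannel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .montage import MontageSpec

__all__ = ["EEGRecording"]


@dataclass
class EEGRecording:
    """Channels x samples EEG matrix (microvolts) with montage metadata.

    Parameters
    ----------
    data
        Real matrix with one row per montage channel.
    fs
        Sampling rate in Hz. Must exceed twice the highest analysis band
        edge; 60 Hz is the hard floor (the high band ends at 30 Hz).
    montage
        Electrode layout; ``data`` rows follow ``montage.channel_names``.
    condition
        Optional mental-state label (``"resting"``, ``"fatigue"``, ...).
    subject_id
        Optional subject identifier.
    """

    data: np.ndarray
    fs: float
    montage: MontageSpec
    condition: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage defines "
                f"{self.montage.n_channels} channels"
            )
        if self.fs < 60.0:
            raise ValueError(f"sampling rate {self.fs} Hz below 60 Hz minimum")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> tuple[str, ...]:
        return self.montage.channel_names

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """Copy of the recording with ``data`` replaced, metadata kept."""
        return replace(self, data=data)
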