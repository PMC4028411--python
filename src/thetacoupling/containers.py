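"""Trial-epoch containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Epochs:
    """Multi-trial time series in sensor or source space.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        One row of channels per trial.  "Channels" are MEG sensors before
        beamforming and grid voxels (virtual electrodes) after.
    fs : float
        Sampling rate in Hz.
    tmin : float
        Time of the first sample in seconds, relative to cue onset
        (negative values are pre-cue).
    """

    data: np.ndarray
    fs: float
    tmin: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Epochs.data must be 3-D (trials, channels, times), got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds relative to cue onset."""
        return self.tmin + np.arange(self.n_times) / self.fs

    def trial(self, i: int) -> "TrialEpoch":
        return TrialEpoch(data=self.data[i], fs=self.fs, tmin=self.tmin)


@dataclass
class TrialEpoch:
    """A single trial's (channels, times) slab; see :class:`Epochs`.

    Each retrieval trial contains both analysis windows: the final second
    of pre-cue fixation (the baseline condition) and a post-cue segment
    (the cue condition), so condition labels attach to windows, not trials.
    """

    data: np.ndarray
    fs: float
    tmin: float
    condition: str | None = field(default=None)

    @property
    def n_times(self) -> int:
        return self.data.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_times) / self.fs
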