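"""Band-pass filtering, analytic signals, band power, and trial windows.

All filtering is zero-phase (forward-backward Butterworth), so band-passed
series keep their timing and instantaneous phase is meaningful.  Analysis
windows are half-open sample ranges ``[start, stop)``; window times in
seconds are rounded to the nearest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt, hilbert

from .containers import TrialEpoch

#: filter order of the Butterworth prototype (per pass; forward-backward
#: application squares the magnitude response)
FILTER_ORDER = 4


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band (Hz)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})")

    def check_feasible(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name!r} ({self.low}-{self.high} Hz) infeasible at fs={fs} Hz (Nyquist {fs / 2} Hz)"
            )


#: canonical bands of the retrieval analysis
THETA = BandDefinition("theta", 4.0, 8.0)
LOW_GAMMA = BandDefinition("low_gamma", 30.0, 45.0)
HIGH_GAMMA = BandDefinition("high_gamma", 65.0, 85.0)


@dataclass(frozen=True)
class ConditionWindows:
    """The two analysis windows, in seconds relative to cue onset.

    Defaults are the final 1 s of pre-cue fixation and the 0.5-1.5 s
    post-cue segment.  Both windows must be equally long (1 s) so that
    finite-sample bias of the coupling metrics cancels in the
    cue-minus-baseline contrast.
    """

    baseline: tuple[float, float] = (-1.0, 0.0)
    cue: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        for name, (t0, t1) in (("baseline", self.baseline), ("cue", self.cue)):
            if not np.isclose(t1 - t0, 1.0, atol=1e-9):
                raise ValueError(f"{name} window must be 1.0 s long, got [{t0}, {t1}]")

    def sample_slices(self, tmin: float, fs: float, n_times: int) -> dict[str, slice]:
        """Half-open sample slices for both windows within an epoch."""
        out = {}
        for name, (t0, t1) in (("baseline", self.baseline), ("cue", self.cue)):
            start = int(round((t0 - tmin) * fs))
            stop = int(round((t1 - tmin) * fs))
            if start < 0 or stop > n_times:
                raise ValueError(
                    f"epoch too short: {name} window [{t0}, {t1}] s needs samples "
                    f"[{start}, {stop}) but epoch has {n_times} samples from tmin={tmin}"
                )
            out[name] = slice(start, stop)
        return out


@dataclass
class AnalyticBandSignal:
    """Complex analytic signal of a band-passed series.

    ``values.real`` is the band-passed series itself; ``abs(values)`` its
    instantaneous amplitude; ``angle(values)`` its instantaneous phase,
    wrapped to (-pi, pi].
    """

    values: np.ndarray
    band: BandDefinition | None
    fs: float

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)


def _design(band: BandDefinition, fs: float) -> np.ndarray:
    band.check_feasible(fs)
    return butter(FILTER_ORDER, [band.low, band.high], btype="band", fs=fs, output="sos")


def transient_samples(band: BandDefinition, fs: float) -> int:
    """Rough length of the filter transient: two cycles of the band's low edge."""
    return int(round(2 * fs / band.low))


def bandpass(series: np.ndarray, band: BandDefinition, fs: float, axis: int = -1) -> np.ndarray:
    """Zero-phase band-pass filter (Butterworth order 4, applied twice).

    The forward-backward pass cancels group delay, so features of in-band
    components stay at their original latency.  The series must be longer
    than three filter transients.
    """
    series = np.asarray(series, dtype=float)
    sos = _design(band, fs)
    n = series.shape[axis]
    min_len = 3 * transient_samples(band, fs)
    if n <= min_len:
        raise ValueError(
            f"series of {n} samples too short for {band.name} filtering at fs={fs} "
            f"(need > {min_len} samples, i.e. > 3 transients of the {band.low} Hz edge)"
        )
    return sosfiltfilt(sos, series, axis=axis)


def analytic(series: np.ndarray, band: BandDefinition | None = None, fs: float = np.nan,
             axis: int = -1) -> AnalyticBandSignal:
    """Analytic signal (Hilbert transform) of a band-limited series.

    The caller is responsible for band-limiting; pass ``band`` to record
    which band the phases belong to.
    """
    series = np.asarray(series, dtype=float)
    return AnalyticBandSignal(values=hilbert(series, axis=axis), band=band, fs=fs)


def band_power(series: np.ndarray, band: BandDefinition, fs: float,
               window: tuple[int, int] | slice | None = None, axis: int = -1) -> np.ndarray:
    """Mean squared band-passed signal over a sample window.

    Convention: power is the time-averaged square of the zero-phase
    band-passed series (a unit-amplitude in-band sinusoid gives 0.5).
    ``window`` is a half-open sample range ``[start, stop)`` into the
    filtered series; the whole series is filtered first so that the window
    is free of filter edge transients when interior.
    """
    filtered = bandpass(series, band, fs, axis=axis)
    if window is not None:
        if isinstance(window, tuple):
            window = slice(*window)
        if window.start is not None and window.stop is not None and window.stop <= window.start:
            raise ValueError(f"empty window {window}")
        filtered = np.take(filtered, np.arange(*window.indices(filtered.shape[axis])), axis=axis)
        if filtered.shape[axis] == 0:
            raise ValueError("window selects no samples")
    return np.mean(filtered**2, axis=axis)


def extract_windows(trial: TrialEpoch, windows: ConditionWindows) -> tuple[np.ndarray, np.ndarray]:
    """Crop one trial's baseline and cue segments.

    Returns ``(baseline, cue)`` arrays, each with exactly ``round(1.0*fs)``
    samples along the last axis (480 samples at 480 Hz).
    """
    slices = windows.sample_slices(trial.tmin, trial.fs, trial.n_times)
    return trial.data[..., slices["baseline"]], trial.data[..., slices["cue"]]
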