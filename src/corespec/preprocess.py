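"""Sensor-space preprocessing: notch filtering, segment selection, noise
covariance estimation.

The notch is a zero-phase (forward-backward) Butterworth band-stop applied
at the powerline frequency and its harmonics below Nyquist.  Analysis
segments are the first artifact-free window of the requested length, where
"artifact-free" means every channel stays below an amplitude threshold —
an explicit, reproducible proxy for the visual inspection used in practice.
The noise covariance comes from an empty-room recording, shrunk toward its
diagonal to guarantee positive definiteness at desk-scale durations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import Recording
from .exceptions import (
    ConfigurationError,
    NoCleanSegmentError,
    NotPositiveDefiniteError,
)


@dataclass
class NoiseCovariance:
    """Symmetric positive-definite sensor noise covariance (tesla^2)."""

    matrix: np.ndarray
    shrinkage: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ConfigurationError("covariance must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-20):
            raise ConfigurationError("covariance must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def is_positive_definite(self) -> bool:
        try:
            np.linalg.cholesky(self.matrix)
            return True
        except np.linalg.LinAlgError:
            return False

    def whitener(self) -> np.ndarray:
        """Inverse matrix square root C^(-1/2) via eigendecomposition."""
        eigval, eigvec = np.linalg.eigh(self.matrix)
        if eigval.min() <= 0:
            raise NotPositiveDefiniteError(
                "noise covariance is not positive definite; "
                "increase the shrinkage"
            )
        return (eigvec / np.sqrt(eigval)) @ eigvec.T


def _notch_sos(
    rate: float, base_freq: float, n_harmonics: int, bandwidth: float
) -> np.ndarray:
    nyquist = rate / 2.0
    sections = []
    for k in range(1, n_harmonics + 1):
        f0 = base_freq * k
        if f0 + bandwidth / 2.0 >= nyquist:
            raise ConfigurationError(
                f"harmonic {k} ({f0:g} Hz) with bandwidth {bandwidth:g} Hz "
                f"reaches Nyquist ({nyquist:g} Hz)"
            )
        sos = signal.butter(
            2,
            [f0 - bandwidth / 2.0, f0 + bandwidth / 2.0],
            btype="bandstop",
            fs=rate,
            output="sos",
        )
        sections.append(sos)
    return np.vstack(sections)


def notch_filter(
    recording: Recording,
    base_freq: float = 50.0,
    n_harmonics: int | None = None,
    bandwidth: float = 2.0,
) -> Recording:
    """Zero-phase band-stop at `base_freq` and its harmonics.

    ``n_harmonics=None`` fits as many harmonics as lie below Nyquist.
    Signal length is preserved (forward-backward filtering with default
    padding).  Raises if an explicitly requested harmonic reaches Nyquist.
    """
    nyquist = recording.rate / 2.0
    if n_harmonics is None:
        n_harmonics = int(np.floor((nyquist - bandwidth) / base_freq))
        if n_harmonics < 1:
            raise ConfigurationError(
                f"base frequency {base_freq:g} Hz does not fit below "
                f"Nyquist {nyquist:g} Hz"
            )
    sos = _notch_sos(recording.rate, base_freq, n_harmonics, bandwidth)
    filtered = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return recording.with_data(
        filtered,
        notch={"base_freq": base_freq, "n_harmonics": n_harmonics,
               "bandwidth": bandwidth},
    )


def select_segment(
    recording: Recording,
    duration: float = 30.0,
    amplitude_threshold: np.ndarray | float | None = None,
    mad_factor: float = 10.0,
) -> Recording:
    """First contiguous artifact-free window of `duration` seconds.

    A sample is clean when |x| stays below the per-channel threshold on
    every channel; the default threshold is ``mad_factor`` (10) times each
    channel's median absolute deviation about the median, i.e. about 6.7
    Gaussian sigma — far above ordinary fluctuation maxima over minutes of
    data, yet well below genuine artifact bursts.  The chosen
    offset is recorded in the annotations.  Raises
    :class:`NoCleanSegmentError` if no such window exists — never a silent
    truncation.
    """
    n_window = int(round(duration * recording.rate))
    if n_window > recording.n_samples:
        raise ConfigurationError(
            f"requested {duration:g} s segment from a "
            f"{recording.duration:g} s recording"
        )
    data = recording.data
    if amplitude_threshold is None:
        med = np.median(data, axis=1, keepdims=True)
        mad = np.median(np.abs(data - med), axis=1, keepdims=True)
        threshold = mad_factor * mad
    else:
        threshold = np.asarray(amplitude_threshold, dtype=float)
        if threshold.ndim == 0:
            threshold = np.full((data.shape[0], 1), float(threshold))
        else:
            threshold = threshold.reshape(data.shape[0], 1)
    clean = np.all(np.abs(data) < threshold, axis=0)
    # first run of n_window consecutive clean samples, via prefix sums
    bad = (~clean).astype(np.int64)
    prefix = np.concatenate([[0], np.cumsum(bad)])
    window_bad = prefix[n_window:] - prefix[:-n_window]
    offsets = np.flatnonzero(window_bad == 0)
    if offsets.size == 0:
        raise NoCleanSegmentError(
            f"no artifact-free {duration:g} s window below the amplitude "
            f"threshold"
        )
    start = int(offsets[0])
    segment = data[:, start:start + n_window]
    return recording.with_data(
        segment, segment_offset_s=start / recording.rate,
        segment_duration_s=duration,
    )


def estimate_noise_covariance(
    empty_room: Recording,
    shrinkage: float = 0.1,
    min_duration: float = 10.0,
) -> NoiseCovariance:
    """Sample covariance of the demeaned empty-room channels, shrunk toward
    its diagonal: ``C_hat = (1 - s) C + s diag(C)``.

    Shrinkage 1 gives an exactly diagonal matrix; the default 0.1 keeps the
    estimate positive definite even for short recordings.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ConfigurationError("shrinkage must lie in [0, 1]")
    if empty_room.duration < min_duration:
        raise ConfigurationError(
            f"empty-room recording too short: {empty_room.duration:g} s "
            f"< {min_duration:g} s"
        )
    x = empty_room.data - empty_room.data.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / (x.shape[1] - 1)
    shrunk = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    result = NoiseCovariance(matrix=shrunk, shrinkage=shrinkage)
    if not result.is_positive_definite():
        raise NotPositiveDefiniteError(
            "shrunk covariance still not positive definite; "
            "increase shrinkage or record longer"
        )
    return result
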