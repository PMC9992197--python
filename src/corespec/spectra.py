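"""ROI spectral estimation: Welch PSD, band integration, relative power.

The per-ROI power spectral density is the Welch PSD (Hann taper, density
scaling, 5 s windows with 50% overlap by default) computed per vertex and
averaged over the ROI's vertices ("power-first"; averaging the time series
first would suffer phase cancellation between vertices).  Band powers
integrate PSD bins over the analysis bands; relative power divides each
band by the summed power of all analyzed bands, giving values in [0, 1]
that sum to 1 per (subject, ROI) and are invariant to any global amplitude
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .bands import DEFAULT_BANDS, BandScheme
from .containers import SourceSpace
from .exceptions import ConfigurationError
from .rois import ROI_NAMES, hemisphere

__all__ = [
    "BandScheme",
    "DEFAULT_BANDS",
    "PSDMatrix",
    "welch_psd",
    "roi_psd",
    "band_power",
    "relative_psd",
    "power_table_row",
]


@dataclass
class PSDMatrix:
    """ROI x frequency-bin matrix of absolute PSD (power per Hz)."""

    values: np.ndarray      # (n_rois, n_bins), non-negative
    freqs: np.ndarray       # (n_bins,) Hz
    roi_names: tuple[str, ...]
    window_s: float
    overlap: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.shape != (len(self.roi_names), self.freqs.size):
            raise ConfigurationError("PSD matrix shape mismatch")
        if np.any(self.values < 0):
            raise ConfigurationError("PSD values must be non-negative")


def welch_psd(
    time_series: np.ndarray,
    rate: float,
    window_s: float = 5.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with Hann taper and density scaling.

    Accepts a single series or a (n_series, n_samples) matrix; returns
    ``(freqs, psd)`` with bin spacing ``1 / window_s``.  The integral of
    the PSD over all bins approximates the signal variance.
    """
    x = np.asarray(time_series, dtype=float)
    nperseg = int(round(window_s * rate))
    if x.shape[-1] < nperseg:
        raise ConfigurationError(
            f"series of {x.shape[-1]} samples shorter than one "
            f"{window_s:g} s window ({nperseg} samples)"
        )
    if not 0.0 <= overlap < 1.0:
        raise ConfigurationError("overlap must lie in [0, 1)")
    freqs, psd = signal.welch(
        x,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def roi_psd(
    source_ts: np.ndarray,
    atlas: SourceSpace,
    rate: float,
    window_s: float = 5.0,
    overlap: float = 0.5,
    reduction: str = "power",
) -> PSDMatrix:
    """Per-ROI PSD of a source time-series matrix (vertices x samples).

    ``reduction="power"`` (default) averages per-vertex PSDs over the
    ROI's vertices; ``"mean"`` computes the PSD of the mean time series
    instead (kept for comparison; subject to phase cancellation).  Rows
    follow the canonical 26-ROI order.
    """
    source_ts = np.asarray(source_ts, dtype=float)
    if source_ts.shape[0] != atlas.n:
        raise ConfigurationError(
            f"source matrix has {source_ts.shape[0]} rows but the atlas "
            f"has {atlas.n} vertices"
        )
    if reduction not in ("power", "mean"):
        raise ConfigurationError(f"unknown reduction {reduction!r}")
    for roi in ROI_NAMES:
        if atlas.roi_vertices(roi).size == 0:
            raise ConfigurationError(f"ROI {roi!r} has no vertices")

    if reduction == "power":
        freqs, vertex_psd = welch_psd(source_ts, rate, window_s, overlap)
        rows = np.vstack(
            [vertex_psd[atlas.roi_vertices(roi)].mean(axis=0) for roi in ROI_NAMES]
        )
    else:
        means = np.vstack(
            [source_ts[atlas.roi_vertices(roi)].mean(axis=0) for roi in ROI_NAMES]
        )
        freqs, rows = welch_psd(means, rate, window_s, overlap)
    return PSDMatrix(
        values=rows, freqs=freqs, roi_names=ROI_NAMES,
        window_s=window_s, overlap=overlap,
    )


def band_power(
    psd_matrix: PSDMatrix, band_scheme: BandScheme = DEFAULT_BANDS
) -> pd.DataFrame:
    """Absolute band power per ROI: sum of in-band PSD bins times bin width.

    Raises if any band extends beyond the highest available bin (use
    ``band_scheme.effective(rate)`` first to drop such bands).
    """
    freqs = psd_matrix.freqs
    f_max = freqs.max()
    for band in band_scheme:
        if band.f_hi > f_max:
            raise ConfigurationError(
                f"band {band.name!r} ([{band.f_lo}, {band.f_hi}] Hz) exceeds "
                f"the spectral range (max bin {f_max:g} Hz)"
            )
    df_bin = 1.0 / psd_matrix.window_s
    masks = band_scheme.bin_assignment(freqs)
    powers = {
        name: psd_matrix.values[:, mask].sum(axis=1) * df_bin
        for name, mask in masks.items()
    }
    return pd.DataFrame(powers, index=list(psd_matrix.roi_names))


def relative_psd(band_powers: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Normalize band powers to relative power in [0, 1].

    Each row (ROI) is divided by its sum over the analyzed bands, so rows
    sum to exactly 1.  All-zero rows are an error (the normalization is
    undefined).
    """
    df = pd.DataFrame(band_powers)
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ConfigurationError("band powers must be non-negative")
    totals = values.sum(axis=1)
    if np.any(totals == 0):
        bad = df.index[totals == 0].tolist()
        raise ConfigurationError(
            f"all-zero band powers (relative power undefined) for rows {bad}"
        )
    return df.div(totals, axis=0)


def power_table_row(
    relative: pd.DataFrame, subject_id: str, group: str | None = None
) -> pd.DataFrame:
    """Long-format rows for one subject: subject_id, roi, hemisphere, band, value."""
    long = (
        relative.rename_axis("roi")
        .reset_index()
        .melt(id_vars="roi", var_name="band", value_name="value")
    )
    long.insert(0, "subject_id", subject_id)
    long["hemisphere"] = [hemisphere(r) for r in long["roi"]]
    if group is not None:
        long.insert(1, "group", group)
    return long[
        (["subject_id", "group"] if group is not None else ["subject_id"])
        + ["roi", "hemisphere", "band", "value"]
    ]
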