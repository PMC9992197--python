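"""Core in-memory containers: sensor array, source space, recording.

Units are SI throughout the package: positions in meters, magnetic data in
tesla, dipole moments in ampere-meters, sampling rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .exceptions import ConfigurationError, ShapeMismatchError
from .rois import ROI_NAMES

_UNIT_TOL = 1e-9


def _check_unit_rows(vectors: np.ndarray, what: str) -> None:
    norms = np.linalg.norm(vectors, axis=1)
    if not np.allclose(norms, 1.0, atol=_UNIT_TOL):
        worst = float(np.abs(norms - 1.0).max())
        raise ConfigurationError(
            f"{what} must be unit-norm (worst deviation {worst:.3e})"
        )


@dataclass
class SensorArray:
    """Magnetometer array: positions (m) and unit pointing orientations."""

    names: list[str]
    positions: np.ndarray     # (n, 3) meters
    orientations: np.ndarray  # (n, 3) unit vectors

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        n = len(self.names)
        if self.positions.shape != (n, 3) or self.orientations.shape != (n, 3):
            raise ShapeMismatchError(
                f"sensor array shapes inconsistent with {n} names: "
                f"positions {self.positions.shape}, "
                f"orientations {self.orientations.shape}"
            )
        if n < 8:
            raise ConfigurationError(f"need at least 8 sensors, got {n}")
        _check_unit_rows(self.orientations, "sensor orientations")

    @property
    def n(self) -> int:
        return len(self.names)


@dataclass
class SourceSpace:
    """Cortical source space: vertex positions, outward normals, ROI labels.

    Every one of the 26 canonical ROI names must be represented by at least
    one vertex; vertices not belonging to any ROI carry the label
    ``"unlabeled"``.
    """

    positions: np.ndarray  # (m, 3) meters
    normals: np.ndarray    # (m, 3) unit vectors
    labels: list[str]      # length m

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        m = len(self.labels)
        if self.positions.shape != (m, 3) or self.normals.shape != (m, 3):
            raise ShapeMismatchError(
                f"source space shapes inconsistent with {m} labels"
            )
        _check_unit_rows(self.normals, "vertex normals")
        present = set(self.labels)
        missing = [name for name in ROI_NAMES if name not in present]
        if missing:
            raise ConfigurationError(f"ROIs with no vertex: {missing}")
        self._label_index: dict[str, np.ndarray] = {}
        labels_arr = np.asarray(self.labels)
        for name in ROI_NAMES:
            self._label_index[name] = np.flatnonzero(labels_arr == name)

    @property
    def n(self) -> int:
        return len(self.labels)

    def roi_vertices(self, roi: str) -> np.ndarray:
        """Indices of the vertices labeled `roi` (canonical name)."""
        try:
            return self._label_index[roi]
        except KeyError:
            raise KeyError(f"unknown ROI {roi!r}") from None


@dataclass
class Recording:
    """Multichannel MEG recording: channels x samples, in tesla."""

    array: SensorArray
    data: np.ndarray  # (n_channels, n_samples) tesla
    rate: float       # Hz
    annotations: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.array.n:
            raise ShapeMismatchError(
                f"data shape {self.data.shape} does not match "
                f"{self.array.n} sensors"
            )
        if not self.rate > 0:
            raise ConfigurationError(f"rate must be positive, got {self.rate}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def with_data(self, data: np.ndarray, **extra_annotations: Any) -> "Recording":
        """Copy of the recording with replaced data and merged annotations."""
        return Recording(
            array=self.array,
            data=data,
            rate=self.rate,
            annotations={**self.annotations, **extra_annotations},
        )
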