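"""HDF5 recording container, lead-field cache, and manifest I/O.

Container layout (one file per recording):

    /sensors/positions     (n, 3) float64, meters
    /sensors/orientations  (n, 3) float64, unit vectors
    /sensors/names         (n,) variable-length strings
    /data                  (n_channels, n_samples) float64, tesla
    attrs: rate (Hz), annotations (JSON string)

An optional adapter exports to the FIF format when `mne` is installed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import Recording, SensorArray
from .exceptions import MissingDataError
from .forward import HeadSphere, LeadField

FORMAT_VERSION = 1


def write_recording(path: str | Path, recording: Recording) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["rate"] = recording.rate
        f.attrs["annotations"] = json.dumps(recording.annotations)
        sensors = f.create_group("sensors")
        sensors.create_dataset("positions", data=recording.array.positions)
        sensors.create_dataset("orientations", data=recording.array.orientations)
        sensors.create_dataset(
            "names", data=np.array(recording.array.names, dtype=object),
            dtype=h5py.string_dtype(),
        )
        f.create_dataset("data", data=recording.data)
    return path


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise MissingDataError(f"recording file not found: {path}")
    with h5py.File(path, "r") as f:
        array = SensorArray(
            names=[n.decode() if isinstance(n, bytes) else str(n)
                   for n in f["sensors/names"][()]],
            positions=f["sensors/positions"][()],
            orientations=f["sensors/orientations"][()],
        )
        return Recording(
            array=array,
            data=f["data"][()],
            rate=float(f.attrs["rate"]),
            annotations=json.loads(f.attrs.get("annotations", "{}")),
        )


def geometry_hash(lead_field: LeadField) -> str:
    """Stable content hash of a lead field (cache key)."""
    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(lead_field.matrix).tobytes())
    digest.update(np.ascontiguousarray(lead_field.sphere.center).tobytes())
    digest.update(np.float64(lead_field.sphere.radius).tobytes())
    return digest.hexdigest()[:16]


def write_lead_field(path: str | Path, lead_field: LeadField) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["key"] = geometry_hash(lead_field)
        f.create_dataset("matrix", data=lead_field.matrix)
        f.create_dataset("sphere_center", data=lead_field.sphere.center)
        f.attrs["sphere_radius"] = lead_field.sphere.radius
    return path


def read_lead_field(path: str | Path) -> LeadField:
    with h5py.File(Path(path), "r") as f:
        return LeadField(
            matrix=f["matrix"][()],
            sphere=HeadSphere(
                center=f["sphere_center"][()],
                radius=float(f.attrs["sphere_radius"]),
            ),
        )


MANIFEST_COLUMNS = [
    "subject_id", "group", "sex", "onset_age", "course_months",
    "seizure_count", "FSIQ", "VCI", "PRI", "WMI", "PSI",
]


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False, columns=[
        c for c in MANIFEST_COLUMNS if c in manifest.columns
    ] + [c for c in manifest.columns if c not in MANIFEST_COLUMNS])
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingDataError(f"manifest not found: {path}")
    return pd.read_csv(path)


def file_checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def export_fif(recording: Recording, path: str | Path) -> Path:
    """Export a recording to FIF via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError(
            "FIF export requires the optional 'mne' dependency "
            "(pip install corespec[fif])"
        ) from exc
    info = mne.create_info(
        ch_names=list(recording.array.names),
        sfreq=recording.rate,
        ch_types="mag",
    )
    raw = mne.io.RawArray(recording.data, info, verbose="error")
    for ch, pos, ori in zip(
        raw.info["chs"], recording.array.positions, recording.array.orientations
    ):
        loc = np.zeros(12)
        loc[:3] = pos
        loc[3:6] = ori
        ch["loc"] = loc
    path = Path(path)
    raw.save(path, overwrite=True, verbose="error")
    return path
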