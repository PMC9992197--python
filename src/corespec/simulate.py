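"""Synthetic MEG cohort generator with known ground-truth spectral effects.

Generates three groups of subjects (CI: cognitively impaired patients,
CNI: non-impaired patients, HC: healthy controls), each with

* a sensor-level resting-state recording produced from a generative
  cortical source model: per-vertex 1/f background plus band-limited
  Gaussian oscillators whose amplitudes are scaled per (group, ROI, band)
  by an effect map — the controlled truth every downstream stage is
  checked against;
* clinical covariates (sex, onset age, epilepsy course, seizure count,
  WISC-IV indices) drawn from the published group means and SDs.

Oscillators are coherent across the vertices of one ROI (a shared waveform),
emulating local field coherence within a functional region; the 1/f
background is independent per vertex.  Sensor data are the lead-field
projection of the sources plus white sensor noise and a 50 Hz line
component.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning, so an identical design yields a
bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import stats as sp_stats

from .bands import DEFAULT_BANDS, BandScheme
from .containers import Recording, SensorArray, SourceSpace
from .exceptions import ConfigurationError, ShapeMismatchError
from .rois import HIGH_BAND_DECREASE_ROIS, ROI_BASENAMES, ROI_NAMES

GROUPS = ("CI", "CNI", "HC")

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

# Published per-group clinical summaries (mean, SD).  Patients' WISC-IV
# indices; healthy controls have no seizure history and their full-scale IQ
# lies in the 90-110 normal range.
CLINICAL_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    "CI": {
        "onset_age": (7.98, 1.45),
        "course_months": (6.08, 4.14),
        "seizure_count": (3.17, 1.34),
        "FSIQ": (84.63, 4.79),
        "VCI": (82.96, 9.12),
        "PRI": (88.5, 10.44),
        "WMI": (88.29, 8.47),
        "PSI": (93.25, 15.88),
    },
    "CNI": {
        "onset_age": (8.80, 1.74),
        "course_months": (5.40, 7.75),
        "seizure_count": (3.125, 2.95),
        "FSIQ": (107.79, 8.03),
        "VCI": (104.96, 12.23),
        "PRI": (111.79, 7.37),
        "WMI": (100.79, 10.01),
        "PSI": (106.16, 14.54),
    },
    # HC WISC indices: the normal range is stated as 90-110; modeled as a
    # Gaussian centered in that range, truncated to it.
    "HC": {
        "onset_age": (8.35, 1.92),  # age at recording; no seizure onset
        "FSIQ": (100.0, 5.0),
        "VCI": (100.0, 5.0),
        "PRI": (100.0, 5.0),
        "WMI": (100.0, 5.0),
        "PSI": (100.0, 5.0),
    },
}

_FEMALE_FRACTION = {"CI": 14 / 24, "CNI": 11 / 24, "HC": 0.5}

EffectMap = dict[str, dict[tuple[str, str], float]]


def null_effect_map() -> EffectMap:
    """All multipliers 1: the three groups are statistically exchangeable."""
    return {g: {} for g in GROUPS}


def default_effect_map(
    delta_up: float = 1.5,
    alpha_down: float = 0.7,
    theta_up: float = 1.3,
    high_down: float = 0.7,
) -> EffectMap:
    """Effect map reproducing the direction of the published group findings.

    Patients show increased delta and decreased alpha oscillatory amplitude
    across all 26 ROIs (strongest delta in CI, additional theta elevation in
    CNI), and decreased high-band (beta and above) amplitude in the insula,
    superior/middle temporal, and parahippocampal regions.
    """
    effects: EffectMap = {g: {} for g in GROUPS}
    high_bands = ("beta", "gamma1", "gamma2", "ripple", "fast_ripple")
    for roi in ROI_NAMES:
        for group in ("CI", "CNI"):
            effects[group][(roi, "delta")] = delta_up if group == "CI" else (
                1.0 + (delta_up - 1.0) * 0.6
            )
            effects[group][(roi, "alpha")] = alpha_down
        effects["CNI"][(roi, "theta")] = theta_up
        if roi.rsplit(".", 1)[0] in HIGH_BAND_DECREASE_ROIS:
            for band in high_bands:
                effects["CI"][(roi, band)] = high_down
                effects["CNI"][(roi, band)] = high_down
    return effects


def planted_effect_map(
    group: str, roi: str, band: str, multiplier: float
) -> EffectMap:
    """Single-cell effect map used for recovery and power experiments."""
    effects = null_effect_map()
    effects[group][(roi, band)] = multiplier
    return effects


def effect_multiplier(
    effects: EffectMap, group: str, roi: str, band: str
) -> float:
    return effects.get(group, {}).get((roi, band), 1.0)


@dataclass
class CohortDesign:
    """Full parameterization of a synthetic cohort.

    Defaults are the desk-scale study conditions (64 sensors, 600 Hz, 60 s,
    520 vertices); :meth:`paper_scale` carries the acquisition-scale values
    (275 sensors, 6 kHz, 2 min, ~15k vertices).  Oscillator amplitudes are
    RMS dipole moments in A*m; sensor noise and line amplitude are in tesla.
    """

    n_per_group: int = 24
    sampling_rate: float = 600.0
    duration: float = 60.0
    n_sensors: int = 64
    n_vertices: int = 520
    head_radius: float = 0.09
    empty_room_duration: float = 30.0
    background_exponent: float = 1.0
    background_amplitude: float = 10e-9
    osc_amplitudes: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 8e-9,
            "theta": 7e-9,
            "alpha": 10e-9,
            "beta": 4e-9,
            "gamma1": 2e-9,
            "gamma2": 1.5e-9,
            "ripple": 1.0e-9,
            "fast_ripple": 0.8e-9,
        }
    )
    sensor_noise_sd: float = 2e-13
    line_freq: float = 50.0
    line_amplitude: float = 1e-12
    effects: EffectMap = field(default_factory=default_effect_map)
    band_scheme: BandScheme = field(default_factory=lambda: DEFAULT_BANDS)
    master_seed: int = 0

    # memory guard: vertex-chunked synthesis bounds the transient footprint,
    # but the sensor-level recording itself must fit comfortably.
    # 2 GiB of float64 admits the acquisition-scale profile (275 ch x 2 min
    # x 6 kHz ~ 1.6 GiB) while rejecting runaway configurations.
    _MAX_SENSOR_SAMPLES = 2 * 1024 * 1024 * 1024 // 8

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ConfigurationError("duration and sampling rate must be > 0")
        for group, cells in self.effects.items():
            if group not in GROUPS:
                raise ConfigurationError(f"unknown group in effect map: {group}")
            for (roi, band), mult in cells.items():
                if mult < 0:
                    raise ConfigurationError(
                        f"negative multiplier for {group}/{roi}/{band}"
                    )
        n_samples = int(round(self.duration * self.sampling_rate))
        if self.n_sensors * n_samples > self._MAX_SENSOR_SAMPLES:
            raise ConfigurationError(
                "recording too large for the memory budget: "
                f"{self.n_sensors} sensors x {n_samples} samples"
            )

    @classmethod
    def paper_scale(cls, **overrides) -> "CohortDesign":
        """Acquisition-scale design: 275 sensors, 6 kHz, 2 min, 15k vertices."""
        params = dict(
            n_per_group=24,
            sampling_rate=6000.0,
            duration=120.0,
            n_sensors=275,
            n_vertices=15000,
            empty_room_duration=120.0,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def smoke(cls, **overrides) -> "CohortDesign":
        """Tiny profile for fast end-to-end checks."""
        params = dict(
            n_per_group=2,
            duration=32.0,
            n_vertices=78,
        )
        params.update(overrides)
        return cls(**params)

    def replace(self, **changes) -> "CohortDesign":
        return replace(self, **changes)


@dataclass
class SubjectRecord:
    """One subject's clinical covariates."""

    subject_id: str
    group: str
    sex: str
    onset_age: float
    course_months: float
    seizure_count: float
    FSIQ: float
    VCI: float
    PRI: float
    WMI: float
    PSI: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        for key in ("FSIQ", "VCI", "PRI", "WMI", "PSI"):
            value = getattr(self, key)
            if np.isfinite(value) and value <= 0:
                raise ConfigurationError(f"{key} must be positive")
        if self.group == "CI" and not self.FSIQ < 90:
            raise ConfigurationError("CI subjects must have FSIQ < 90")
        if self.group == "CNI" and not self.FSIQ > 90:
            raise ConfigurationError("CNI subjects must have FSIQ > 90")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "sex": self.sex,
            "onset_age": self.onset_age,
            "course_months": self.course_months,
            "seizure_count": self.seizure_count,
            "FSIQ": self.FSIQ,
            "VCI": self.VCI,
            "PRI": self.PRI,
            "WMI": self.WMI,
            "PSI": self.PSI,
        }


# ---------------------------------------------------------------------------
# geometry


def make_sensor_array(
    count: int = 275, head_radius: float = 0.09, seed: int = 0
) -> SensorArray:
    """Quasi-uniform magnetometer helmet on an upper spherical cap.

    Sensors sit on a sphere of radius ``1.1 * head_radius``, radially
    oriented, covering polar angles up to ~115 degrees (a whole-head
    helmet).  Deterministic given ``seed`` (the seed sets the azimuthal
    phase of the Fibonacci winding).
    """
    if count < 8:
        raise ConfigurationError(f"need at least 8 sensors, got {count}")
    if head_radius <= 0:
        raise ConfigurationError("head_radius must be positive")
    phase = np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi)
    z_min = np.cos(np.deg2rad(115.0))
    k = np.arange(count)
    z = 1.0 - (1.0 - z_min) * (k + 0.5) / count
    phi = _GOLDEN_ANGLE * k + phase
    s = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    radius = 1.1 * head_radius
    names = [f"MEG{i + 1:03d}" for i in range(count)]
    return SensorArray(names=names, positions=radius * dirs, orientations=dirs)


def _hemisphere_fibonacci(n: int, seed: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the x > 0 hemisphere."""
    phase = np.random.default_rng(seed).uniform(0.0, 1.0)
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    # azimuth measured from the +x axis, restricted to (-pi/2, pi/2)
    frac = np.mod(k * (np.sqrt(5.0) - 1.0) / 2.0 + phase, 1.0)
    phi = (frac - 0.5) * np.pi
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _tilted_normals(dirs: np.ndarray, tilt_deg: float) -> np.ndarray:
    """Outward normals tilted from radial toward the local azimuth.

    Purely radial dipoles are magnetically silent in a spherical conductor,
    so cortical normals are modeled with a fixed tangential component.
    """
    z_axis = np.array([0.0, 0.0, 1.0])
    tangents = np.cross(np.broadcast_to(z_axis, dirs.shape), dirs)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    small = norms[:, 0] < 1e-12
    if np.any(small):
        tangents[small] = np.array([1.0, 0.0, 0.0])
        norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    tangents /= norms
    alpha = np.deg2rad(tilt_deg)
    normals = np.cos(alpha) * dirs + np.sin(alpha) * tangents
    return normals / np.linalg.norm(normals, axis=1, keepdims=True)


def make_source_space(
    n_vertices: int = 520,
    seed: int = 0,
    head_radius: float = 0.09,
    shell_fraction: float = 0.78,
    normal_tilt_deg: float = 60.0,
) -> SourceSpace:
    """Spherical-shell source space with 26 mirrored contiguous ROI patches.

    Half the vertices are placed quasi-uniformly on the right (x > 0)
    hemisphere of an inner shell; the other half are their mirror images
    across the x = 0 plane.  Right-hemisphere vertices are labeled by their
    nearest of 13 patch centers (giving contiguous Voronoi patches); left
    labels and normals are the exact mirror, so bilateral ROI centroids
    reflect across x = 0.
    """
    if n_vertices < 52:
        raise ConfigurationError(
            f"need at least 52 vertices (2 per ROI), got {n_vertices}"
        )
    m = n_vertices // 2
    shell = shell_fraction * head_radius
    right_dirs = _hemisphere_fibonacci(m, seed)
    centers = _hemisphere_fibonacci(13, seed + 1)

    # nearest patch center (max cosine) -> contiguous patches
    assignment = np.argmax(right_dirs @ centers.T, axis=1)
    # guarantee every patch at least one vertex
    for j in range(13):
        if not np.any(assignment == j):
            assignment[int(np.argmax(right_dirs @ centers[j]))] = j

    right_normals = _tilted_normals(right_dirs, normal_tilt_deg)
    mirror = np.diag([-1.0, 1.0, 1.0])
    left_dirs = right_dirs @ mirror
    left_normals = right_normals @ mirror

    dirs = np.vstack([right_dirs, left_dirs])
    normals = np.vstack([right_normals, left_normals])
    labels = [f"{ROI_BASENAMES[j]}.R" for j in assignment] + [
        f"{ROI_BASENAMES[j]}.L" for j in assignment
    ]

    if n_vertices % 2:  # odd count: one extra vertex on the midline
        extra_dir = np.array([0.0, 0.0, 1.0])
        j = int(np.argmax(centers @ extra_dir))
        dirs = np.vstack([dirs, extra_dir])
        normals = np.vstack([normals, _tilted_normals(extra_dir[None], normal_tilt_deg)])
        labels.append(f"{ROI_BASENAMES[j]}.R")

    return SourceSpace(positions=shell * dirs, normals=normals, labels=labels)


# ---------------------------------------------------------------------------
# signal synthesis


def _unit_rows(x: np.ndarray) -> np.ndarray:
    """Scale each row to unit sample standard deviation (in place)."""
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    x /= sd
    return x


def one_over_f_noise(
    rng: np.random.Generator,
    n_series: int,
    n_samples: int,
    rate: float,
    exponent: float = 1.0,
    f_floor: float = 1.0,
) -> np.ndarray:
    """Rows of unit-SD noise with power spectrum ~ 1/f**exponent.

    Synthesized in the frequency domain; amplitudes below ``f_floor`` are
    clamped to the floor value to keep the variance finite, and DC is zero.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    amp = np.maximum(freqs, f_floor) ** (-exponent / 2.0)
    amp[0] = 0.0
    coef = rng.standard_normal((n_series, freqs.size)) + 1j * rng.standard_normal(
        (n_series, freqs.size)
    )
    x = np.fft.irfft(coef * amp, n=n_samples, axis=-1)
    return _unit_rows(x)


def band_limited_noise(
    rng: np.random.Generator,
    n_series: int,
    n_samples: int,
    rate: float,
    f_lo: float,
    f_hi: float,
) -> np.ndarray:
    """Rows of unit-SD Gaussian noise strictly band-limited to [f_lo, f_hi]."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not np.any(mask):
        raise ConfigurationError(
            f"no spectral support in [{f_lo}, {f_hi}] Hz at rate {rate} Hz"
        )
    coef = np.zeros((n_series, freqs.size), dtype=complex)
    nb = int(mask.sum())
    coef[:, mask] = rng.standard_normal((n_series, nb)) + 1j * rng.standard_normal(
        (n_series, nb)
    )
    x = np.fft.irfft(coef, n=n_samples, axis=-1)
    return _unit_rows(x)


def simulate_subject(
    design: CohortDesign,
    source_space: SourceSpace,
    array: SensorArray,
    lead_field: np.ndarray,
    group: str,
    rng: np.random.Generator,
    chunk_size: int = 1024,
) -> Recording:
    """Simulate one subject's sensor-level recording.

    Source model per vertex: 1/f background (independent across vertices)
    plus, for every analysis band below Nyquist, a band-limited Gaussian
    oscillator shared by all vertices of the ROI and scaled by the group's
    (ROI, band) multiplier.  Sensor data are the lead-field projection plus
    white sensor noise and a 50 Hz sinusoidal line component.  Vertex
    synthesis is chunked so memory stays bounded at any source-space size.
    """
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}")
    lead_field = np.asarray(lead_field, dtype=float)
    if lead_field.shape != (array.n, source_space.n):
        raise ShapeMismatchError(
            f"lead field shape {lead_field.shape} does not match "
            f"{array.n} sensors x {source_space.n} sources"
        )
    rate = design.sampling_rate
    n_samples = int(round(design.duration * rate))
    bands = design.band_scheme.effective(rate) if any(
        b.f_hi > rate / 2 for b in design.band_scheme
    ) else design.band_scheme

    data = np.zeros((array.n, n_samples))

    # ROI-coherent oscillators: one waveform per (ROI, band)
    for roi in ROI_NAMES:
        idx = source_space.roi_vertices(roi)
        if idx.size == 0:
            continue
        roi_signal = np.zeros(n_samples)
        for band in bands:
            w = band_limited_noise(rng, 1, n_samples, rate, band.f_lo, band.f_hi)[0]
            amp = design.osc_amplitudes.get(band.name, 0.0) * effect_multiplier(
                design.effects, group, roi, band.name
            )
            roi_signal += amp * w
        # all vertices of the ROI share the waveform: project once
        data += np.outer(lead_field[:, idx].sum(axis=1), roi_signal)

    # 1/f background, independent per vertex, chunked
    for start in range(0, source_space.n, chunk_size):
        stop = min(start + chunk_size, source_space.n)
        bg = one_over_f_noise(
            rng, stop - start, n_samples, rate, design.background_exponent
        )
        bg *= design.background_amplitude
        data += lead_field[:, start:stop] @ bg

    # sensor noise and powerline contamination
    data += design.sensor_noise_sd * rng.standard_normal(data.shape)
    if design.line_amplitude > 0:
        t = np.arange(n_samples) / rate
        phases = rng.uniform(0.0, 2.0 * np.pi, size=array.n)
        data += design.line_amplitude * np.sin(
            2.0 * np.pi * design.line_freq * t[None, :] + phases[:, None]
        )

    return Recording(array=array, data=data, rate=rate, annotations={"group": group})


def simulate_empty_room(
    array: SensorArray,
    duration: float,
    noise_sd: float,
    rng: np.random.Generator,
    rate: float = 600.0,
) -> Recording:
    """Empty-room recording: zero-mean white sensor noise, no sources."""
    if duration <= 0:
        raise ConfigurationError(f"duration must be positive, got {duration}")
    n_samples = int(round(duration * rate))
    data = noise_sd * rng.standard_normal((array.n, n_samples))
    return Recording(
        array=array, data=data, rate=rate, annotations={"kind": "empty_room"}
    )


# ---------------------------------------------------------------------------
# clinical covariates


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lower: float = -np.inf,
    upper: float = np.inf,
    size=None,
):
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return sp_stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


_WISC_BOUNDS = {
    # group -> index -> (lower, upper) truncation
    "CI": {"FSIQ": (70.0, 90.0)},
    "CNI": {"FSIQ": (90.0, 140.0)},
    "HC": {k: (90.0, 110.0) for k in ("FSIQ", "VCI", "PRI", "WMI", "PSI")},
}


def sample_clinical(
    design: CohortDesign,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "S000",
) -> SubjectRecord:
    """Draw one subject's clinical covariates for `group`.

    Covariates are independent Gaussians with the published group means and
    SDs, truncated where the group definition demands it (CI: FSIQ < 90,
    CNI: FSIQ > 90, HC: WISC indices within the 90-110 normal range; course
    and seizure count nonnegative, onset age within the syndrome's 4-14 y
    range).  Healthy controls have no seizure-related covariates (NaN).
    """
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}")
    summary = CLINICAL_SUMMARIES[group]
    bounds = _WISC_BOUNDS[group]

    def draw(key: str, lower=-np.inf, upper=np.inf) -> float:
        mean, sd = summary[key]
        lo, hi = bounds.get(key, (lower, upper))
        return float(_truncated_normal(rng, mean, sd, lo, hi))

    sex = "F" if rng.uniform() < _FEMALE_FRACTION[group] else "M"
    onset = draw("onset_age", 4.0, 14.0)
    if group == "HC":
        course = float("nan")
        seizures = float("nan")
    else:
        course = draw("course_months", 0.0)
        seizures = draw("seizure_count", 0.0)
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        sex=sex,
        onset_age=onset,
        course_months=course,
        seizure_count=seizures,
        FSIQ=draw("FSIQ", 40.0),
        VCI=draw("VCI", 40.0),
        PRI=draw("PRI", 40.0),
        WMI=draw("WMI", 40.0),
        PSI=draw("PSI", 40.0),
    )


# ---------------------------------------------------------------------------
# cohort orchestration


def geometry_seeds(master_seed: int) -> tuple[int, int]:
    """Deterministic (sensor, source-space) construction seeds."""
    state = np.random.SeedSequence(master_seed).generate_state(2)
    return int(state[0] % (2**31)), int(state[1] % (2**31))


def iter_cohort(
    design: CohortDesign,
    source_space: SourceSpace,
    array: SensorArray,
    lead_field: np.ndarray,
) -> Iterator[tuple[SubjectRecord, Recording]]:
    """Yield (clinical record, recording) per subject, group by group.

    Subjects are generated lazily so only one recording lives in memory at a
    time.  The stream is fully determined by ``design.master_seed``.
    """
    root = np.random.SeedSequence(design.master_seed).spawn(len(GROUPS))
    counter = 0
    for group, group_seq in zip(GROUPS, root):
        children = group_seq.spawn(design.n_per_group)
        for child in children:
            counter += 1
            clin_seq, rec_seq = child.spawn(2)
            subject_id = f"S{counter:03d}"
            record = sample_clinical(
                design, group, np.random.default_rng(clin_seq), subject_id
            )
            recording = simulate_subject(
                design,
                source_space,
                array,
                lead_field,
                group,
                np.random.default_rng(rec_seq),
            )
            recording.annotations["subject_id"] = subject_id
            yield record, recording


def cohort_empty_room(
    design: CohortDesign, array: SensorArray
) -> Recording:
    """The cohort's empty-room recording (deterministic from the design)."""
    seq = np.random.SeedSequence(design.master_seed, spawn_key=(999,))
    return simulate_empty_room(
        array,
        design.empty_room_duration,
        design.sensor_noise_sd,
        np.random.default_rng(seq),
        rate=design.sampling_rate,
    )
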