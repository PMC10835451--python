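"""Core domain types, validation and file I/O for RSOM quality control.

Conventions
-----------
* Depths are in micrometres (um), measured from the first recorded sample.
  Sample ``k`` of an A-line maps to the one-way depth
  ``k * speed_of_sound / sampling_rate`` (optoacoustic propagation is
  one-way, not pulse-echo).  With the defaults (1500 m/s, 1 GS/s) one
  depth sample spans 1.5 um.
* Scans are 3-D cubes ``[n_fast, n_slow, n_samples]`` of signed pressure
  amplitudes in arbitrary units.
* The acquisition order is a unidirectional raster: for each slow index
  ``j`` the fast axis is swept ``i = 0..n_fast-1``, so A-line ``(i, j)``
  has timestamp ``(j * n_fast + i) / pulse_rate``.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

SCHEMA_VERSION = "1"

__all__ = [
    "SCHEMA_VERSION",
    "RsomQCError",
    "DataValidationError",
    "ScanKind",
    "AcquisitionOrder",
    "SystemConfig",
    "RawScan",
    "SurfaceMap",
    "MotionGraph",
    "MotionMetrics",
    "ThresholdSet",
    "QCReport",
    "save_scan",
    "load_scan",
    "save_motion_csv",
    "load_motion_csv",
    "write_report",
    "load_report",
]


class RsomQCError(Exception):
    """Base class for all rsomqc errors."""


class DataValidationError(RsomQCError, ValueError):
    """A domain-type invariant was violated."""


class ScanKind(str, enum.Enum):
    FULL = "full"
    SUTURE = "suture"
    POINT = "point"


class AcquisitionOrder(str, enum.Enum):
    #: unidirectional raster, fast axis swept within each slow step
    FAST_WITHIN_SLOW = "fast-within-slow"
    #: serpentine data may be declared but is not produced by the simulator
    SERPENTINE = "serpentine"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DataValidationError(msg)


@dataclass(frozen=True)
class SystemConfig:
    """Acquisition geometry and electronics of one RSOM system.

    Parameters are strictly positive; ``band_low < band_high`` and the
    band must sit below the Nyquist frequency of ``sampling_rate``.
    """

    n_fast: int = 266
    n_slow: int = 135
    sampling_rate: float = 1.0e9  # samples / s
    speed_of_sound: float = 1500.0  # m / s
    step_fast: float = 15.0  # um
    step_slow: float = 15.0  # um
    pulse_rate: float = 500.0  # Hz (laser repetition rate)
    center_freq: float = 50.0e6  # Hz
    band_low: float = 10.0e6  # Hz
    band_high: float = 120.0e6  # Hz
    focal_depth: float = 300.0  # um

    def __post_init__(self) -> None:
        for name in (
            "n_fast", "n_slow", "sampling_rate", "speed_of_sound",
            "step_fast", "step_slow", "pulse_rate", "center_freq",
            "band_low", "band_high", "focal_depth",
        ):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0, f"SystemConfig.{name} must be finite and > 0, got {v!r}")
        _require(int(self.n_fast) == self.n_fast and int(self.n_slow) == self.n_slow,
                 "n_fast and n_slow must be integers")
        _require(self.band_low < self.band_high < self.sampling_rate / 2,
                 "need band_low < band_high < sampling_rate/2")

    @property
    def dz(self) -> float:
        """One-way depth per sample, um."""
        return self.speed_of_sound / self.sampling_rate * 1e6

    @property
    def n_alines(self) -> int:
        return int(self.n_fast) * int(self.n_slow)

    @property
    def scan_duration(self) -> float:
        """Total acquisition time of one raster, s."""
        return self.n_alines / self.pulse_rate

    def aline_times(self) -> np.ndarray:
        """Timestamps of every A-line in acquisition order, s."""
        return np.arange(self.n_alines) / self.pulse_rate

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RawScan:
    """A raw 3-D sinogram plus its acquisition metadata.

    ``amplitudes`` has shape ``[n_fast, n_slow, n_samples]`` and must match
    ``config``.  ``kind`` constrains the shape further: suture scans are a
    single fast line (``n_slow == 1``) and point measurements hold repeated
    shots along the slow axis (``n_fast == 1``).
    """

    amplitudes: np.ndarray
    config: SystemConfig
    kind: ScanKind = ScanKind.FULL
    acquisition_order: AcquisitionOrder = AcquisitionOrder.FAST_WITHIN_SLOW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes)
        self.kind = ScanKind(self.kind)
        self.acquisition_order = AcquisitionOrder(self.acquisition_order)
        a = self.amplitudes
        _require(a.ndim == 3, f"amplitudes must be 3-D, got ndim={a.ndim}")
        _require(a.shape[0] == self.config.n_fast and a.shape[1] == self.config.n_slow,
                 f"amplitudes shape {a.shape[:2]} does not match config "
                 f"({self.config.n_fast}, {self.config.n_slow})")
        _require(a.shape[2] > 1, "need more than one sample per A-line")
        if self.kind is ScanKind.SUTURE:
            _require(self.config.n_slow == 1, "suture scans must have n_slow == 1")
        if self.kind is ScanKind.POINT:
            _require(self.config.n_fast == 1, "point measurements must have n_fast == 1")
        _require(bool(np.isfinite(a).all()), "amplitudes contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.amplitudes.shape[2]

    @property
    def depth_window(self) -> float:
        """Maximum recordable depth, um."""
        return (self.n_samples - 1) * self.config.dz

    def alines(self) -> np.ndarray:
        """View of the cube as ``[n_alines, n_samples]`` in acquisition order."""
        a = self.amplitudes
        if self.acquisition_order is AcquisitionOrder.FAST_WITHIN_SLOW:
            return a.transpose(1, 0, 2).reshape(-1, a.shape[2])
        raise DataValidationError(
            f"acquisition order {self.acquisition_order} is declared but unsupported")


@dataclass
class SurfaceMap:
    """Per-scan-position skin-surface depth in um with a validity mask."""

    depth: np.ndarray  # [n_fast, n_slow], um
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        _require(self.depth.ndim == 2, "surface depth must be 2-D")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.depth.shape, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        _require(self.valid_mask.shape == self.depth.shape,
                 "valid_mask shape does not match depth")
        _require(bool(np.isfinite(self.depth[self.valid_mask]).all()),
                 "valid surface depths contain non-finite values")

    def check_bounds(self, scan: RawScan) -> None:
        d = self.depth[self.valid_mask]
        _require(bool(((d >= 0) & (d <= scan.n_samples * scan.config.dz)).all()),
                 "surface depth outside the recordable window")


@dataclass
class MotionGraph:
    """Vertical displacement versus acquisition time.

    ``displacement`` is in um, ordered by acquisition time with one entry
    per ``dt`` seconds.
    """

    displacement: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float).ravel()
        _require(self.displacement.size > 1, "motion graph needs length > 1")
        _require(bool(np.isfinite(self.displacement).all()),
                 "motion graph contains non-finite values")
        _require(np.isfinite(self.dt) and self.dt > 0, "dt must be finite and > 0")

    def __len__(self) -> int:
        return self.displacement.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt

    @property
    def duration(self) -> float:
        return len(self) * self.dt

    def resampled(self, times: np.ndarray) -> "MotionGraph":
        """Linear resampling onto new (uniformly spaced) timestamps."""
        times = np.asarray(times, dtype=float)
        _require(times.size > 1, "need more than one resampling timestamp")
        disp = np.interp(times, self.times, self.displacement)
        return MotionGraph(disp, float(times[1] - times[0]))


@dataclass(frozen=True)
class MotionMetrics:
    """Summary motion statistics of one scan.

    ``m_std`` is the population standard deviation of the motion graph
    about its mean, ``m_max`` the maximum absolute deviation from the
    mean, and ``q_motion = m_std + beta * m_max``.
    """

    m_std: float
    m_max: float
    q_motion: float
    beta: float

    def __post_init__(self) -> None:
        _require(self.m_std >= 0, "m_std must be >= 0")
        _require(self.m_max >= self.m_std - 1e-9,
                 "m_max (max |deviation|) cannot be below m_std")
        _require(math.isclose(self.q_motion, self.m_std + self.beta * self.m_max,
                              rel_tol=1e-9, abs_tol=1e-9),
                 "q_motion != m_std + beta * m_max")


@dataclass(frozen=True)
class ThresholdSet:
    """Calibrated decision thresholds for the motion quality index.

    ``beta = t_std / t_max`` and therefore
    ``tq_motion = t_std + beta * t_max = 2 * t_std``.
    """

    t_std: float  # um
    t_max: float  # um
    beta: float  # dimensionless
    tq_motion: float  # um
    r_snr: float  # dB

    def __post_init__(self) -> None:
        _require(self.t_std > 0 and self.t_max > 0, "thresholds must be > 0")
        _require(math.isclose(self.beta, self.t_std / self.t_max, rel_tol=1e-9),
                 "beta != t_std / t_max")
        _require(math.isclose(self.tq_motion, self.t_std + self.beta * self.t_max,
                              rel_tol=1e-9),
                 "tq_motion != t_std + beta * t_max")

    @classmethod
    def from_t(cls, t_std: float, t_max: float, r_snr: float) -> "ThresholdSet":
        beta = t_std / t_max
        return cls(t_std=t_std, t_max=t_max, beta=beta,
                   tq_motion=t_std + beta * t_max, r_snr=r_snr)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(**{k: float(d[k]) for k in ("t_std", "t_max", "beta", "tq_motion", "r_snr")})


@dataclass
class QCReport:
    """Machine-readable pass/fail record for one scan."""

    scan_id: str
    suture_snr: float  # dB
    gate_pass: bool
    m_std: float  # um
    m_max: float  # um
    q_motion: float  # um
    thresholds: ThresholdSet
    motion_pass: bool
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if isinstance(self.thresholds, dict):
            self.thresholds = ThresholdSet.from_dict(self.thresholds)
        _require(self.motion_pass == (self.q_motion <= self.thresholds.tq_motion),
                 "motion_pass inconsistent with q_motion vs tq_motion")
        _require(self.gate_pass == (self.suture_snr >= self.thresholds.r_snr),
                 "gate_pass inconsistent with suture_snr vs r_snr")
        self.flags = [str(f) for f in self.flags]

    def to_dict(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "suture_snr": float(self.suture_snr),
            "gate_pass": bool(self.gate_pass),
            "m_std": float(self.m_std),
            "m_max": float(self.m_max),
            "q_motion": float(self.q_motion),
            "thresholds": self.thresholds.to_dict(),
            "motion_pass": bool(self.motion_pass),
            "flags": list(self.flags),
        }


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = [f.name for f in dataclasses.fields(SystemConfig)]


def save_scan(scan: RawScan, path: str | Path) -> Path:
    """Write a scan to a single self-describing HDF5 container.

    Layout: dataset ``/amplitudes`` (float32) and root attributes holding
    every :class:`SystemConfig` field plus ``kind``, ``acquisition_order``
    and ``schema_version``.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("amplitudes", data=np.asarray(scan.amplitudes, dtype=np.float32))
        for name in _CONFIG_FIELDS:
            f.attrs[name] = getattr(scan.config, name)
        f.attrs["kind"] = scan.kind.value
        f.attrs["acquisition_order"] = scan.acquisition_order.value
        f.attrs["schema_version"] = SCHEMA_VERSION
        if scan.meta:
            f.attrs["meta_json"] = json.dumps(scan.meta)
    return path


def load_scan(path: str | Path) -> RawScan:
    """Load and validate a scan written by :func:`save_scan`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "amplitudes" not in f:
            raise DataValidationError(f"{path}: missing dataset '/amplitudes'")
        amplitudes = f["amplitudes"][...]
        missing = [n for n in _CONFIG_FIELDS + ["kind", "acquisition_order"]
                   if n not in f.attrs]
        if missing:
            raise DataValidationError(f"{path}: missing attributes {missing}")
        cfg_kwargs = {}
        for name in _CONFIG_FIELDS:
            v = f.attrs[name]
            cfg_kwargs[name] = int(v) if name in ("n_fast", "n_slow") else float(v)
        kind = str(f.attrs["kind"])
        order = str(f.attrs["acquisition_order"])
        meta = json.loads(f.attrs["meta_json"]) if "meta_json" in f.attrs else {}
    if not np.isfinite(amplitudes).all():
        raise DataValidationError(f"{path}: dataset '/amplitudes' contains non-finite values")
    config = SystemConfig(**cfg_kwargs)
    return RawScan(amplitudes=amplitudes, config=config, kind=ScanKind(kind),
                   acquisition_order=AcquisitionOrder(order), meta=meta)


def save_motion_csv(graph: MotionGraph, path: str | Path) -> Path:
    """Write a motion graph as a two-column CSV ``time_s,displacement_um``."""
    path = Path(path)
    data = np.column_stack([graph.times, graph.displacement])
    np.savetxt(path, data, delimiter=",", header="time_s,displacement_um",
               comments="", fmt="%.9g")
    return path


def load_motion_csv(path: str | Path) -> MotionGraph:
    path = Path(path)
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise DataValidationError(f"{path}: expected two columns time_s,displacement_um")
    t = data[:, 0]
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
        raise DataValidationError(f"{path}: time column is not uniformly sampled")
    return MotionGraph(displacement=data[:, 1], dt=float(steps[0]))


def write_report(report: QCReport, path: str | Path) -> Path:
    """Serialize a validated QC report as JSON (round-trip stable)."""
    # re-run the invariants in case the object was mutated after creation
    QCReport(**{**report.to_dict(), "thresholds": report.thresholds})
    path = Path(path)
    with open(path, "w") as f:
        json.dump(report.to_dict(), f, indent=2)
        f.write("\n")
    return path


def load_report(path: str | Path) -> QCReport:
    with open(path) as f:
        d = json.load(f)
    d["thresholds"] = ThresholdSet.from_dict(d["thresholds"])
    return QCReport(**d)
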