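"""Forward simulator for synthetic RSOM scans.

Generates skin-phantom raster scans, suture reference lines and fixed-head
point measurements with controllable vertical motion and additive noise,
so that every stage of the QC pipeline can be exercised without clinical
data.

The acoustic model is deliberately minimal: each absorber contributes a
Gaussian-windowed cosine pulse at the one-way time-of-flight of its
geometric distance to the scan position, weighted by a Gaussian lateral
detection profile.  Vertical motion acts as a rigid depth offset of all
absorbers for a given A-line.  There is no attenuation, dispersion or
fluence modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import gausspulse

from .data_model import (
    DataValidationError,
    MotionGraph,
    RawScan,
    RsomQCError,
    ScanKind,
    SystemConfig,
)

__all__ = [
    "SimulationError",
    "Vessel",
    "SutureSpec",
    "PhantomSpec",
    "MotionModelSpec",
    "make_base_motion",
    "normalize_motion",
    "scale_motion",
    "shape_motion_to_metrics",
    "simulate_scan",
    "make_suture_scan",
    "make_point_scan",
    "make_cohort",
    "standard_config",
    "standard_phantom",
    "standard_motion_spec",
]


class SimulationError(RsomQCError, ValueError):
    pass


@dataclass(frozen=True)
class Vessel:
    """Spherical dermal absorber; size controls its frequency content."""

    center: tuple  # (x um, y um, z um)
    radius: float  # um
    amplitude: float  # signal units

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.amplitude > 0):
            raise DataValidationError("vessel radius and amplitude must be > 0")


@dataclass(frozen=True)
class SutureSpec:
    depth: float  # um
    diameter: float = 100.0  # um
    amplitude: float = 1.0
    slow_center: float | None = None  # um along the slow axis; None -> middle


@dataclass(frozen=True)
class PhantomSpec:
    """Optical-absorber layout of a synthetic forearm patch.

    The melanin layer is a continuous surface absorber with mean depth
    ``surface_mean_depth`` and a linear tilt in um per mm along each axis.
    """

    surface_mean_depth: float = 240.0  # um
    surface_tilt: tuple = (0.0, 0.0)  # um per mm, (fast, slow)
    surface_amplitude: float = 1.0  # 0 disables the surface layer
    vessels: tuple = ()
    suture: SutureSpec | None = None

    def __post_init__(self) -> None:
        if not (self.surface_mean_depth > 0 and self.surface_amplitude >= 0):
            raise DataValidationError("surface depth must be > 0 and amplitude >= 0")
        object.__setattr__(self, "vessels", tuple(self.vessels))


@dataclass(frozen=True)
class MotionModelSpec:
    """Parameters of the physiological base-motion generator.

    The generated displacement is the sum of an arterial-pulsation
    sinusoid, a slower breathing sinusoid, piecewise-constant random jumps
    (Poisson event times, signed uniform amplitudes) and a Gaussian
    random-walk drift.
    """

    pulse_amp: float = 3.0  # um
    pulse_freq: float = 1.0  # Hz
    breath_amp: float = 1.5  # um
    breath_freq: float = 0.25  # Hz
    jump_rate: float = 0.5  # events / s
    jump_amp: float = 5.0  # um
    drift_std: float = 0.0  # um per step
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pulse_amp", "pulse_freq", "breath_amp", "breath_freq",
                     "jump_rate", "jump_amp", "drift_std"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"MotionModelSpec.{name} must be >= 0")


def make_base_motion(spec: MotionModelSpec, duration: float, dt: float) -> MotionGraph:
    """Generate a complex vertical motion pattern, deterministic per seed."""
    if not (duration > dt > 0):
        raise SimulationError("need duration > dt > 0")
    n = int(round(duration / dt))
    if n < 2:
        raise SimulationError("duration too short for the requested dt")
    t = np.arange(n) * dt
    rng = np.random.default_rng(spec.seed)
    disp = spec.pulse_amp * np.sin(2 * np.pi * spec.pulse_freq * t)
    disp = disp + spec.breath_amp * np.sin(2 * np.pi * spec.breath_freq * t)
    # Poisson-thinned jump events; the offset is piecewise constant
    events = rng.random(n) < spec.jump_rate * dt
    jumps = np.zeros(n)
    jumps[events] = rng.uniform(-spec.jump_amp, spec.jump_amp, int(events.sum()))
    disp = disp + np.cumsum(jumps)
    if spec.drift_std > 0:
        disp = disp + np.cumsum(rng.normal(0.0, spec.drift_std, n))
    return MotionGraph(displacement=disp, dt=dt)


def normalize_motion(graph: MotionGraph, target_std: float) -> MotionGraph:
    """Rescale about the mean so the population std equals ``target_std``."""
    x = graph.displacement
    std = float(x.std())
    if std == 0.0:
        raise SimulationError("cannot normalize a constant motion graph")
    mean = x.mean()
    return MotionGraph(mean + (x - mean) * (target_std / std), graph.dt)


def scale_motion(graph: MotionGraph, weight: float) -> MotionGraph:
    """Multiply every displacement by ``weight``."""
    if not np.isfinite(weight):
        raise SimulationError("weight must be finite")
    return MotionGraph(graph.displacement * weight, graph.dt)


def shape_motion_to_metrics(graph: MotionGraph, m_std: float, m_max: float,
                            tol: float = 0.02, max_iter: int = 200) -> MotionGraph:
    """Reshape a graph so its std and max |deviation| hit a target pair.

    Alternates rescaling about the mean with clipping / spiking of the
    extreme deviation until both statistics are within ``tol`` (relative).
    Raises for infeasible targets (``m_max < m_std``).
    """
    if m_max < m_std:
        raise SimulationError(f"infeasible target pair: m_max={m_max} < m_std={m_std}")
    if m_std == 0.0:
        return MotionGraph(np.zeros(len(graph)), graph.dt)
    x = graph.displacement.astype(float).copy()
    if x.std() == 0.0:
        raise SimulationError("base graph is constant")
    for _ in range(max_iter):
        mean = x.mean()
        dev = x - mean
        std = dev.std()
        dev *= m_std / std
        k = int(np.argmax(np.abs(dev)))
        cur_max = abs(dev[k])
        if cur_max > m_max:
            dev = np.clip(dev, -m_max, m_max)
        elif cur_max < m_max:
            dev[k] = math.copysign(m_max, dev[k] if dev[k] != 0 else 1.0)
        x = mean + dev
        dev = x - x.mean()
        if (abs(dev.std() - m_std) <= tol * m_std
                and abs(np.abs(dev).max() - m_max) <= tol * m_max):
            return MotionGraph(x, graph.dt)
    raise SimulationError(
        f"could not shape motion to (m_std={m_std}, m_max={m_max}) within {max_iter} iterations")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

#: default lateral detection width (Gaussian FWHM at focus), um
DEFAULT_BEAM_WIDTH = 30.0
#: lateral support of an absorber, in beam widths
_LATERAL_CUTOFF = 2.0


def _motion_offsets(motion: MotionGraph | None, config: SystemConfig) -> np.ndarray:
    """Per-position vertical offsets as an [n_fast, n_slow] array, um."""
    if motion is None:
        return np.zeros((config.n_fast, config.n_slow))
    if motion.duration < config.scan_duration - motion.dt:
        raise SimulationError(
            f"motion graph ({motion.duration:.3f} s) shorter than the scan "
            f"({config.scan_duration:.3f} s)")
    per_line = motion.resampled(config.aline_times()).displacement
    # acquisition order is fast-within-slow: A-line p = j * n_fast + i
    return per_line.reshape(config.n_slow, config.n_fast).T


def _pulse_cube(k: np.ndarray, depth: np.ndarray, config: SystemConfig,
                fc: float, bw_frac: float) -> np.ndarray:
    """Band-limited pulses centred at the time-of-flight of ``depth`` (um)."""
    tof = depth / config.dz  # fractional sample index
    t = (k - tof[..., None]) / config.sampling_rate
    return gausspulse(t, fc=fc, bw=bw_frac, bwr=-6)


def _vessel_freq(radius: float, config: SystemConfig) -> float:
    """Characteristic frequency of a spherical absorber, clipped to the band."""
    c_um = config.speed_of_sound * 1e6  # um/s
    f = c_um / (4.0 * radius)
    return float(np.clip(f, config.band_low, 0.9 * config.band_high))


def simulate_scan(phantom: PhantomSpec, config: SystemConfig,
                  motion: MotionGraph | None = None, noise_std: float = 0.0,
                  seed: int = 0, n_samples: int = 512,
                  beam_width: float = DEFAULT_BEAM_WIDTH,
                  sensitivity_scale: float | None = None,
                  kind: ScanKind | None = None) -> RawScan:
    """Simulate one raster scan of a phantom.

    Every A-line is the sum over absorbers of a Gaussian-windowed cosine
    pulse (carrier ``config.center_freq``, -6 dB fractional bandwidth
    spanning ``band_low..band_high``) centred at the one-way time-of-flight
    of the absorber depth plus that A-line's motion offset, with additive
    white Gaussian noise.  Deterministic given ``seed``.
    """
    nf, ns = config.n_fast, config.n_slow
    dz = config.dz
    window = (n_samples - 1) * dz
    rng = np.random.default_rng(seed)
    moff = _motion_offsets(motion, config)
    k = np.arange(n_samples, dtype=float)
    xs = np.arange(nf) * config.step_fast  # um
    ys = np.arange(ns) * config.step_slow

    bw_frac = (config.band_high - config.band_low) / config.center_freq
    sigma_lat = beam_width / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # FWHM -> sigma

    def sens(depth: np.ndarray) -> np.ndarray:
        if sensitivity_scale is None:
            return np.ones_like(depth)
        return np.exp(-((depth - config.focal_depth) ** 2) / (2.0 * sensitivity_scale ** 2))

    cube = np.zeros((nf, ns, n_samples))

    if phantom.surface_amplitude > 0:
        surf = (phantom.surface_mean_depth
                + phantom.surface_tilt[0] * xs[:, None] / 1000.0
                + phantom.surface_tilt[1] * ys[None, :] / 1000.0)
        depth = surf + moff
        if depth.min() < 0 or depth.max() > window:
            raise SimulationError("surface absorber outside the recordable window")
        cube += (phantom.surface_amplitude * sens(depth))[..., None] * _pulse_cube(
            k, depth, config, config.center_freq, bw_frac)

    for v in phantom.vessels:
        vx, vy, vz = v.center
        lat2 = (xs[:, None] - vx) ** 2 + (ys[None, :] - vy) ** 2
        w = np.exp(-lat2 / (2.0 * sigma_lat ** 2))
        w[np.sqrt(lat2) > _LATERAL_CUTOFF * beam_width] = 0.0
        if not w.any():
            continue
        vdepth = vz + moff
        if vdepth.min() < 0 or vdepth.max() > window:
            raise SimulationError(f"vessel at z={vz} um outside the recordable window")
        # off-axis contributions arrive at the geometric one-way distance,
        # so delay-and-sum can refocus them
        dist = np.sqrt(lat2 + vdepth ** 2)
        fc_v = _vessel_freq(v.radius, config)
        cube += (v.amplitude * w * sens(vdepth))[..., None] * _pulse_cube(
            k, dist, config, fc_v, 0.6)

    if phantom.suture is not None:
        s = phantom.suture
        y0 = s.slow_center if s.slow_center is not None else float(ys.mean())
        lat2 = np.broadcast_to((ys[None, :] - y0) ** 2, (nf, ns)).copy()
        w = np.exp(-lat2 / (2.0 * sigma_lat ** 2))
        sdepth = s.depth + moff
        if sdepth.min() < 0 or sdepth.max() > window:
            raise SimulationError("suture outside the recordable window")
        dist = np.sqrt(lat2 + sdepth ** 2)
        fc_s = _vessel_freq(s.diameter / 2.0, config)
        cube += (s.amplitude * w * sens(sdepth))[..., None] * _pulse_cube(
            k, dist, config, fc_s, 0.6)

    if noise_std > 0:
        cube = cube + rng.normal(0.0, noise_std, cube.shape)

    if kind is None:
        if ns == 1:
            kind = ScanKind.SUTURE
        elif nf == 1:
            kind = ScanKind.POINT
        else:
            kind = ScanKind.FULL
    return RawScan(amplitudes=cube.astype(np.float32), config=config, kind=kind,
                   meta={"simulated": True, "seed": int(seed),
                         "duration_s": config.scan_duration})


def make_suture_scan(config: SystemConfig, suture_depth: float, amplitude: float = 1.0,
                     noise_std: float = 0.0, seed: int = 0, n_samples: int = 512,
                     sensitivity_scale: float = 150.0) -> RawScan:
    """Simulate the suture reference line scan (``n_slow == 1``).

    The 100 um suture produces the same pulse on every fast position, with
    a Gaussian depth-sensitivity falloff peaking at ``config.focal_depth``
    (scale ``sensitivity_scale``, um).
    """
    cfg = replace(config, n_slow=1)
    dz = cfg.dz
    if not (0 <= suture_depth <= (n_samples - 1) * dz):
        raise SimulationError("suture depth outside the recordable window")
    rng = np.random.default_rng(seed)
    k = np.arange(n_samples, dtype=float)
    bw_frac = (cfg.band_high - cfg.band_low) / cfg.center_freq
    amp_eff = amplitude * math.exp(
        -((suture_depth - cfg.focal_depth) ** 2) / (2.0 * sensitivity_scale ** 2))
    t = (k - suture_depth / dz) / cfg.sampling_rate
    line = amp_eff * gausspulse(t, fc=cfg.center_freq, bw=bw_frac, bwr=-6)
    cube = np.broadcast_to(line, (cfg.n_fast, 1, n_samples)).copy()
    if noise_std > 0:
        cube = cube + rng.normal(0.0, noise_std, cube.shape)
    return RawScan(amplitudes=cube.astype(np.float32), config=cfg, kind=ScanKind.SUTURE,
                   meta={"simulated": True, "seed": int(seed),
                         "suture_depth_um": float(suture_depth),
                         "duration_s": cfg.scan_duration})


def make_point_scan(config: SystemConfig, depth: float, motion: MotionGraph | None,
                    amplitude: float = 1.0, noise_std: float = 0.0, seed: int = 0,
                    n_samples: int = 512) -> RawScan:
    """Simulate a fixed-head point measurement (``n_fast == 1``).

    The slow axis holds the repeated shots; the single absorber at
    ``depth`` moves by the motion graph over the acquisition.
    """
    cfg = replace(config, n_fast=1)
    phantom = PhantomSpec(surface_mean_depth=depth, surface_amplitude=amplitude)
    return simulate_scan(phantom, cfg, motion=motion, noise_std=noise_std, seed=seed,
                         n_samples=n_samples, kind=ScanKind.POINT)


def make_cohort(n_scans: int, metric_targets: Sequence[tuple],
                config: SystemConfig, phantom: PhantomSpec, seed: int = 0,
                noise_std: float = 0.01, n_samples: int = 512) -> list:
    """Simulate a cohort with injected motion matching (m_std, m_max) targets.

    Each scan's injected graph matches its target pair within 5 %; the
    ground-truth graphs are returned for recovery testing.
    """
    if n_scans != len(metric_targets):
        raise SimulationError("n_scans must equal len(metric_targets)")
    out = []
    for idx, (m_std, m_max) in enumerate(metric_targets):
        if m_max < m_std:
            raise SimulationError(
                f"target {idx}: infeasible pair m_max={m_max} < m_std={m_std}")
        spec = standard_motion_spec(seed=seed * 10007 + idx)
        base = make_base_motion(spec, duration=config.scan_duration + 1.0 / config.pulse_rate,
                                dt=1.0 / config.pulse_rate)
        if m_std == 0.0:
            graph = MotionGraph(np.zeros(len(base)), base.dt)
        else:
            graph = shape_motion_to_metrics(base, m_std, m_max)
        scan = simulate_scan(phantom, config, motion=graph, noise_std=noise_std,
                             seed=seed * 10007 + idx, n_samples=n_samples)
        out.append((scan, graph))
    return out


# ---------------------------------------------------------------------------
# Presets used by the CLI, the test-suite and the acceptance script
# ---------------------------------------------------------------------------

def standard_config(n_fast: int = 64, n_slow: int = 16) -> SystemConfig:
    """Desk-scale acquisition geometry with the published system constants."""
    return SystemConfig(n_fast=n_fast, n_slow=n_slow, focal_depth=240.0)


def standard_phantom() -> PhantomSpec:
    """Melanin surface plus a handful of dermal vessels of mixed caliber."""
    return PhantomSpec(
        surface_mean_depth=240.0,
        surface_tilt=(4.0, 3.0),
        surface_amplitude=1.0,
        vessels=(
            Vessel(center=(300.0, 120.0, 420.0), radius=20.0, amplitude=0.8),
            Vessel(center=(600.0, 120.0, 480.0), radius=15.0, amplitude=0.7),
            Vessel(center=(450.0, 90.0, 520.0), radius=6.0, amplitude=0.5),
            Vessel(center=(750.0, 150.0, 450.0), radius=5.0, amplitude=0.5),
        ),
    )


def standard_motion_spec(seed: int = 0) -> MotionModelSpec:
    """Pulse-dominated physiological motion with sparse jumps."""
    return MotionModelSpec(pulse_amp=3.0, pulse_freq=1.1, breath_amp=1.0,
                           breath_freq=0.3, jump_rate=1.0, jump_amp=4.0,
                           drift_std=0.02, seed=seed)


def calibration_base_motion(duration: float, dt: float, seed: int = 0,
                            m_std: float = 5.0, m_max: float = 40.0,
                            bump_width: float = 0.01) -> MotionGraph:
    """Base motion graph for the threshold-calibration ladder.

    Physiological pulse/breath/jump motion plus one brief jitter excursion
    (a Gaussian bump of ``bump_width`` seconds), jointly scaled so the
    graph's std and maximum absolute deviation hit ``(m_std, m_max)`` -
    by default 5 um / 40 um, the statistics of a measured volunteer base
    graph (weights 0.1..3 then span stds 0.5-15 um and maxima 4-120 um).
    """
    if m_max < m_std:
        raise SimulationError("need m_max >= m_std")
    g = make_base_motion(standard_motion_spec(seed), duration, dt)
    x = g.displacement - g.displacement.mean()
    if x.std() == 0.0:
        raise SimulationError("base graph is constant")
    x = x / x.std()
    t = g.times
    rng = np.random.default_rng(seed + 987654321)
    t0 = float(rng.uniform(0.3, 0.7)) * g.duration
    bump = np.exp(-((t - t0) ** 2) / (2.0 * bump_width ** 2))
    s, a = m_std, 0.0
    for _ in range(200):
        y = s * x + a * bump
        dev = y - y.mean()
        cur_std = float(dev.std())
        cur_max = float(np.abs(dev).max())
        if (abs(cur_std - m_std) <= 1e-3 * m_std
                and abs(cur_max - m_max) <= 1e-3 * m_max):
            return MotionGraph(y, dt)
        s *= m_std / cur_std
        a += m_max - cur_max
        a = max(a, 0.0)
    raise SimulationError("calibration base motion did not converge; "
                          "try a different seed or a wider bump")
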