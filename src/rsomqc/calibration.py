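"""Simulation study that calibrates the motion-quality thresholds.

A base motion graph is scaled by a ladder of weights, injected into a
clean scan, retrieved and corrected.  Each ladder step is scored by the
zero-lag normalized cross-correlation ``c_n`` between added and retrieved
graphs and by the CNR of the corrected reconstruction.  The thresholds
``t_std`` / ``t_max`` are the (interpolated) motion statistics at which
the corrected CNR first drops 1 dB below the zero-motion reference;
``beta = t_std / t_max`` and ``tq_motion = t_std + beta * t_max``
(algebraically ``2 * t_std``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .correction import inject_motion, retrieve_and_correct
from .data_model import MotionGraph, RawScan, RsomQCError, ThresholdSet
from .motion import DEFAULT_GAUSSIAN_SIGMA, DEFAULT_MEDIAN_WINDOW, motion_metrics
from .recon import ReconGrid, compute_cnr, mip, reconstruct_das

__all__ = [
    "CalibrationError",
    "CalibrationStep",
    "CalibrationResult",
    "default_weights",
    "generate_weighted_motions",
    "cross_corr_index",
    "run_motion_study",
    "determine_thresholds",
    "standard_study_geometry",
]


class CalibrationError(RsomQCError, ValueError):
    pass


def default_weights() -> list:
    """The arithmetic weight ladder 0.1, 0.4, ... in steps of 0.3, <= 3."""
    w = np.arange(0.1, 3.0 + 1e-9, 0.3)
    return [round(float(v), 10) for v in w]


def generate_weighted_motions(base: MotionGraph, weights: Sequence[float] | None = None
                              ) -> list:
    """Scale the base graph by each ladder weight."""
    from .synthetic_rsom import scale_motion

    if weights is None:
        weights = default_weights()
    weights = list(weights)
    if len(weights) == 0:
        raise CalibrationError("empty weight list")
    if any(w <= 0 for w in weights):
        raise CalibrationError("weights must be positive")
    if sorted(weights) != weights:
        raise CalibrationError("weights must be sorted ascending")
    if float(base.displacement.std()) == 0.0:
        raise CalibrationError("base motion graph is constant")
    return [scale_motion(base, w) for w in weights]


def cross_corr_index(ma: MotionGraph, mr: MotionGraph, mode: str = "zero_lag") -> float:
    """Normalized cross-correlation between added and retrieved graphs.

    ``mode="zero_lag"`` (default) is the Pearson form at zero lag, so
    identical graphs score 1 and negated graphs -1.  ``mode="peak"``
    returns the maximum of the normalized cross-correlation over all lags.
    """
    a = np.asarray(ma.displacement, dtype=float)
    b = np.asarray(mr.displacement, dtype=float)
    if a.size != b.size or a.size < 2:
        raise CalibrationError("graphs must have equal length >= 2")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na == 0.0 and nb == 0.0:
        raise CalibrationError("both graphs are constant")
    if na == 0.0 or nb == 0.0:
        return 0.0
    if mode == "zero_lag":
        return float(np.dot(a, b) / (na * nb))
    if mode == "peak":
        corr = np.correlate(a, b, mode="full") / (na * nb)
        return float(corr.max())
    raise CalibrationError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class CalibrationStep:
    weight: float
    m_std: float  # um, of the added graph
    m_max: float  # um
    c_n: float  # added-vs-retrieved correlation
    cnr_db: float  # corrected-image CNR

    def to_dict(self) -> dict:
        return {"weight": self.weight, "m_std": self.m_std, "m_max": self.m_max,
                "c_n": self.c_n, "cnr_db": self.cnr_db}


@dataclass
class CalibrationResult:
    weights: list
    per_step: list  # of CalibrationStep
    reference_cnr_db: float
    thresholds: ThresholdSet | None = None

    def __post_init__(self) -> None:
        stds = [s.m_std for s in self.per_step]
        # strictly increasing with weight, except for the degenerate
        # all-zero ladder where every std is 0
        if any(b < a or (b == a and b > 0) for a, b in zip(stds, stds[1:])):
            raise CalibrationError("per-step m_std must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "weights": list(self.weights),
            "per_step": [s.to_dict() for s in self.per_step],
            "reference_cnr_db": float(self.reference_cnr_db),
            "thresholds": self.thresholds.to_dict() if self.thresholds else None,
        }


def run_motion_study(clean_scan: RawScan, motions: Sequence[MotionGraph],
                     feature_roi: tuple, background_roi: tuple,
                     weights: Sequence[float] | None = None,
                     grid: ReconGrid | None = None,
                     depth_gate: tuple | None = None,
                     min_snr_db: float = 10.0,
                     median_window: tuple = DEFAULT_MEDIAN_WINDOW,
                     gaussian_sigma: tuple = DEFAULT_GAUSSIAN_SIGMA,
                     half_angle_deg: float = 25.0,
                     mip_axis: str = "slow",
                     corr_mode: str = "zero_lag") -> CalibrationResult:
    """Corrupt-correct-score every motion of the ladder.

    For each added graph ``ma_n``: inject it into the clean scan (direct
    A-line shifting), run the surface-based retrieval and correction to get
    ``mr_n``, record ``c_n = cross_corr_index(ma_n, mr_n)`` and the CNR of
    the corrected reconstruction on the given ROIs.  The reference CNR is
    measured on the uncorrupted scan.  Zero added motion reports
    ``c_n = 1.0`` by convention.
    """
    cfg = clean_scan.config
    times = cfg.aline_times()

    def _recon_cnr(scan: RawScan) -> float:
        vol = reconstruct_das(scan, grid=grid, half_angle_deg=half_angle_deg)
        img = mip(vol, axis=mip_axis)
        return compute_cnr(img, feature_roi, background_roi).cnr_db

    if weights is None:
        weights = [float(n) for n in range(len(motions))]
    if len(weights) != len(motions):
        raise CalibrationError("weights and motions must have equal length")
    reference_cnr = _recon_cnr(clean_scan)
    steps = []
    for n, ma in enumerate(motions):
        ma_r = ma if len(ma) == cfg.n_alines else ma.resampled(times)
        met = motion_metrics(ma_r, beta=0.0)
        if float(ma_r.displacement.std()) == 0.0:
            c_n = 1.0
            cnr = _recon_cnr(clean_scan)
        else:
            corrupted = inject_motion(clean_scan, ma_r)
            corrected, mr = retrieve_and_correct(
                corrupted, depth_gate=depth_gate, min_snr_db=min_snr_db,
                median_window=median_window, gaussian_sigma=gaussian_sigma)
            c_n = cross_corr_index(ma_r, mr, mode=corr_mode)
            cnr = _recon_cnr(corrected)
        steps.append(CalibrationStep(weight=float(weights[n]), m_std=met.m_std,
                                     m_max=met.m_max, c_n=c_n, cnr_db=cnr))
    return CalibrationResult(weights=[float(w) for w in weights], per_step=steps,
                             reference_cnr_db=reference_cnr)


def determine_thresholds(result: CalibrationResult, drop_db: float = 1.0,
                         r_snr: float = 45.0) -> ThresholdSet:
    """Locate the 1-dB CNR drop on the ladder and derive the thresholds.

    ``t_std`` is the ``m_std`` at which the corrected CNR first falls below
    ``reference_cnr_db - drop_db``, linearly interpolated between adjacent
    ladder steps; ``t_max`` is the ``m_max`` at the same interpolated
    point.  Raises if the CNR never drops that far within the ladder.
    """
    if not result.per_step:
        raise CalibrationError("empty calibration result")
    target = result.reference_cnr_db - drop_db
    stds = np.array([s.m_std for s in result.per_step])
    maxs = np.array([s.m_max for s in result.per_step])
    cnrs = np.array([s.cnr_db for s in result.per_step])
    below = np.flatnonzero(cnrs < target)
    if below.size == 0:
        raise CalibrationError(
            f"no threshold within ladder: CNR never drops {drop_db} dB below "
            f"the reference ({result.reference_cnr_db:.2f} dB)")
    k = int(below[0])
    if k == 0:
        t_std, t_max = float(stds[0]), float(maxs[0])
    else:
        f = (cnrs[k - 1] - target) / (cnrs[k - 1] - cnrs[k])
        t_std = float(stds[k - 1] + f * (stds[k] - stds[k - 1]))
        t_max = float(maxs[k - 1] + f * (maxs[k] - maxs[k - 1]))
    return ThresholdSet.from_t(t_std=t_std, t_max=t_max, r_snr=r_snr)


def standard_study_geometry(config, z_step: float = 3.0) -> dict:
    """Depth gate, reconstruction grid and CNR ROIs matched to the
    standard phantom of :mod:`rsomqc.synthetic_rsom`.

    The depth gate brackets the 240 um melanin surface by +-30 um (the
    melanin search range of the segmentation; motion carrying the surface
    beyond it is what defeats the correction), the grid covers the dermal
    vessels (330-700 um), the feature ROI encloses the vessels in the
    cross-sectional (fast x depth) MIP and the background ROI sits in the
    absorber-free deep region.  ``min_snr_db`` is set low (6 dB) so that
    failed segmentations keep their raw argmax depth, as the plain
    surface-detection algorithm would.
    """
    dz = config.dz
    surface = 240.0
    depth_gate = (int((surface - 30.0) / dz), int((surface + 31.5) / dz))
    z = np.arange(330.0, 700.0, z_step)
    grid = ReconGrid(x=np.arange(config.n_fast) * config.step_fast,
                     y=np.arange(config.n_slow) * config.step_slow, z=z)

    def zi(v: float) -> int:
        return int(round((v - z[0]) / z_step))

    feature_roi = (12, min(56, config.n_fast), zi(390.0), zi(560.0))
    background_roi = (0, config.n_fast, zi(600.0), z.size)
    return {"depth_gate": depth_gate, "grid": grid, "feature_roi": feature_roi,
            "background_roi": background_roi, "mip_axis": "slow",
            "min_snr_db": 6.0}
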