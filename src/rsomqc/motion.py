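"""Surface-based motion quantification.

The melanin layer produces the strongest signal at every scan position, so
a per-position depth map of its envelope peak gives the motion-disrupted
surface ``S_D``.  Median + Gaussian smoothing yields an artificial
continuous surface ``S_C``; their difference, flattened along acquisition
time, is the vertical motion graph ``M = S_D - S_C``.  The graph is
summarized by its standard deviation ``m_std``, its maximum absolute
deviation from the mean ``m_max`` and the combined quality index
``q_motion = m_std + beta * m_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import hilbert

from .data_model import (
    AcquisitionOrder,
    MotionGraph,
    MotionMetrics,
    RawScan,
    RsomQCError,
    SurfaceMap,
    ThresholdSet,
)

__all__ = [
    "MotionError",
    "MotionClassification",
    "extract_surface",
    "smooth_surface",
    "motion_graph",
    "motion_metrics",
    "classify_motion",
    "DEFAULT_MEDIAN_WINDOW",
    "DEFAULT_GAUSSIAN_SIGMA",
]

# smoothing defaults in scan positions (fast, slow); wide enough to span a
# pulsation period along the slow axis at typical step/pulse rates
DEFAULT_MEDIAN_WINDOW = (15, 9)
DEFAULT_GAUSSIAN_SIGMA = (5.0, 3.0)


class MotionError(RsomQCError, ValueError):
    pass


def _parabolic_offset(y0: float, y1: float, y2: float) -> float:
    """Sub-sample offset of a peak from three log-envelope samples."""
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0.0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def extract_surface(scan: RawScan, depth_gate: tuple | None = None,
                    min_snr_db: float = 10.0) -> SurfaceMap:
    """Locate the motion-disrupted skin surface ``S_D``.

    For every scan position the depth of the maximum envelope amplitude
    inside ``depth_gate`` (a ``(start, stop)`` sample range) is taken as
    the surface, refined by 3-point parabolic interpolation of the
    log-envelope so that sub-sample motion is resolvable.  Positions whose
    peak fails ``min_snr_db`` against the scan noise floor (std of the
    deepest 20 % of samples) are masked invalid and inpainted from the
    nearest valid neighbour.
    """
    nf, ns = scan.config.n_fast, scan.config.n_slow
    n = scan.n_samples
    if depth_gate is None:
        depth_gate = (0, n)
    g0, g1 = int(depth_gate[0]), int(depth_gate[1])
    if not (0 <= g0 < g1 <= n):
        raise MotionError("depth gate must be non-empty and inside the recorded range")
    dz = scan.config.dz

    noise0 = int(round(0.8 * n))
    noise_std = float(scan.amplitudes[:, :, noise0:].std())

    depth = np.empty((nf, ns))
    peak = np.empty((nf, ns))
    # chunk the Hilbert transform over the slow axis to bound memory
    for j in range(ns):
        env = np.abs(hilbert(scan.amplitudes[:, j, g0:g1].astype(float), axis=-1))
        idx = np.argmax(env, axis=-1)
        pk = env[np.arange(nf), idx]
        delta = np.zeros(nf)
        interior = (idx > 0) & (idx < g1 - g0 - 1) & (pk > 0)
        for i in np.flatnonzero(interior):
            k = idx[i]
            y = env[i, k - 1:k + 2]
            if (y > 0).all():
                delta[i] = _parabolic_offset(*np.log(y))
        depth[:, j] = (g0 + idx + delta) * dz
        peak[:, j] = pk

    if noise_std > 0:
        with np.errstate(divide="ignore"):
            snr = 20.0 * np.log10(np.where(peak > 0, peak / noise_std, np.nan))
        valid = np.nan_to_num(snr, nan=-np.inf) >= min_snr_db
    else:
        valid = peak > 0
    if not valid.any():
        raise MotionError("no scan position passed the surface SNR criterion")
    if not valid.all():
        # nearest-valid-neighbour inpainting
        ind = ndimage.distance_transform_edt(~valid, return_distances=False,
                                             return_indices=True)
        depth = depth[tuple(ind)]
    return SurfaceMap(depth=depth, valid_mask=valid)


def smooth_surface(s_d: SurfaceMap,
                   median_window: tuple = DEFAULT_MEDIAN_WINDOW,
                   gaussian_sigma: tuple = DEFAULT_GAUSSIAN_SIGMA) -> SurfaceMap:
    """Smooth ``S_D`` into the artificial continuous surface ``S_C``.

    A 2-D median filter (edge-reflected) removes motion discontinuities and
    isolated outliers; the following Gaussian smoothing removes the
    residual staircase.  Both kernels preserve linear anatomical slopes in
    the interior.  The validity mask is propagated unchanged.
    """
    mw = (int(median_window[0]), int(median_window[1]))
    gs = (float(gaussian_sigma[0]), float(gaussian_sigma[1]))
    if mw[0] < 1 or mw[1] < 1:
        raise MotionError("median window must be >= 1 in both axes")
    if mw[0] > s_d.depth.shape[0] or mw[1] > s_d.depth.shape[1]:
        raise MotionError("median window larger than the surface map")
    sm = ndimage.median_filter(s_d.depth, size=mw, mode="reflect")
    sm = ndimage.gaussian_filter(sm, sigma=gs, mode="reflect")
    return SurfaceMap(depth=sm, valid_mask=s_d.valid_mask.copy())


def motion_graph(s_d: SurfaceMap, s_c: SurfaceMap, dt: float,
                 order: AcquisitionOrder = AcquisitionOrder.FAST_WITHIN_SLOW
                 ) -> MotionGraph:
    """Form ``M = S_D - S_C`` as a time series in acquisition order."""
    if s_d.depth.shape != s_c.depth.shape:
        raise MotionError("surface maps have different shapes")
    if order is not AcquisitionOrder.FAST_WITHIN_SLOW:
        raise MotionError(f"acquisition order {order} unsupported")
    diff = s_d.depth - s_c.depth
    # fast-within-slow: A-line p = j * n_fast + i -> column-major flatten
    series = diff.flatten(order="F")
    return MotionGraph(displacement=series, dt=dt)


def motion_metrics(graph: MotionGraph, beta: float) -> MotionMetrics:
    """Compute ``m_std``, ``m_max`` and ``q_motion = m_std + beta * m_max``.

    ``m_std`` is the population standard deviation about the mean and
    ``m_max`` the maximum absolute deviation from the mean, which makes
    both metrics invariant to a constant depth offset.
    """
    x = graph.displacement
    if x.size < 2:
        raise MotionError("motion graph too short")
    dev = x - x.mean()
    m_std = float(dev.std())
    m_max = float(np.abs(dev).max())
    return MotionMetrics(m_std=m_std, m_max=m_max,
                         q_motion=m_std + beta * m_max, beta=beta)


@dataclass(frozen=True)
class MotionClassification:
    passed: bool
    flags: tuple

    def __iter__(self):
        yield self.passed
        yield self.flags


def classify_motion(metrics: MotionMetrics, thresholds: ThresholdSet,
                    strict: bool = False) -> MotionClassification:
    """Pass/fail against ``tq_motion`` plus per-threshold flags.

    The boundary is closed by default (``q_motion == tq_motion`` passes) so
    that the calibration point itself is accepted; ``strict=True`` makes the
    comparison strict.  Flags report ``m_std > t_std`` and ``m_max > t_max``
    independently of the overall decision.
    """
    if strict:
        passed = metrics.q_motion < thresholds.tq_motion
    else:
        passed = metrics.q_motion <= thresholds.tq_motion
    flags = []
    if metrics.m_std > thresholds.t_std:
        flags.append("m_std_above_t_std")
    if metrics.m_max > thresholds.t_max:
        flags.append("m_max_above_t_max")
    return MotionClassification(passed=passed, flags=tuple(flags))
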