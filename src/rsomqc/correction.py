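"""Vertical motion correction of sinograms and point-measurement tracking.

``correct_scan`` undoes a per-A-line vertical displacement by shifting each
A-line along depth with sub-sample spline interpolation.
``retrieve_and_correct`` chains surface extraction, smoothing, motion-graph
formation and correction.  ``point_displacement`` estimates vertical skin
displacement from repeated A-lines of a fixed-head point measurement via
normalized cross-correlation against the first shot.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .data_model import (
    MotionGraph,
    RawScan,
    RsomQCError,
    ScanKind,
)
from .motion import (
    DEFAULT_GAUSSIAN_SIGMA,
    DEFAULT_MEDIAN_WINDOW,
    extract_surface,
    motion_graph,
    smooth_surface,
)

__all__ = ["CorrectionError", "correct_scan", "inject_motion",
           "retrieve_and_correct", "point_displacement"]

_SPLINE_ORDER = {"linear": 1, "cubic": 3}


class CorrectionError(RsomQCError, ValueError):
    pass


def _shift_alines(scan: RawScan, shift_samples: np.ndarray,
                  interpolation: str) -> RawScan:
    """Resample every A-line at ``k + shift`` (zero-filled outside).

    ``"fourier"`` shifts via the FFT phase ramp (exact for the band-limited
    A-lines) and zeroes the samples that would wrap around; ``"cubic"`` and
    ``"linear"`` use spline interpolation.
    """
    if interpolation != "fourier" and interpolation not in _SPLINE_ORDER:
        raise CorrectionError(f"unknown interpolation {interpolation!r}")
    if not np.any(shift_samples):
        return RawScan(amplitudes=scan.amplitudes.copy(), config=scan.config,
                       kind=scan.kind, acquisition_order=scan.acquisition_order,
                       meta=dict(scan.meta))
    lines = scan.alines().astype(float)
    n_lines, n = lines.shape
    if interpolation == "fourier":
        freqs = np.fft.rfftfreq(n)
        spectrum = np.fft.rfft(lines, axis=1)
        spectrum *= np.exp(2j * np.pi * freqs[None, :] * shift_samples[:, None])
        out = np.fft.irfft(spectrum, n=n, axis=1)
        # emulate zero-fill: blank the samples that wrapped around
        for i in range(n_lines):
            s = shift_samples[i]
            if s > 0:
                out[i, n - int(np.ceil(s)):] = 0.0
            elif s < 0:
                out[i, :int(np.ceil(-s))] = 0.0
    else:
        order = _SPLINE_ORDER[interpolation]
        rows = np.repeat(np.arange(n_lines, dtype=float)[:, None], n, axis=1)
        cols = np.arange(n, dtype=float)[None, :] + shift_samples[:, None]
        out = ndimage.map_coordinates(lines, [rows, cols], order=order,
                                      mode="constant", cval=0.0,
                                      prefilter=order > 1)
    cfg = scan.config
    cube = out.reshape(cfg.n_slow, cfg.n_fast, n).transpose(1, 0, 2)
    return RawScan(amplitudes=cube.astype(np.float32), config=cfg, kind=scan.kind,
                   acquisition_order=scan.acquisition_order,
                   meta=dict(scan.meta))


def correct_scan(scan: RawScan, motion: MotionGraph,
                 interpolation: str = "fourier") -> RawScan:
    """Shift every A-line along depth by ``-motion`` to undo vertical motion.

    ``motion`` must have exactly one entry per A-line (in acquisition
    order).  Displacements are converted to samples and applied with
    sub-sample interpolation (Fourier phase shift by default; ``"cubic"``
    and ``"linear"`` splines available), zero-filling at the edges.
    """
    if len(motion) != scan.config.n_alines:
        raise CorrectionError(
            f"motion length {len(motion)} != number of A-lines {scan.config.n_alines}")
    shift = motion.displacement / scan.config.dz
    out = _shift_alines(scan, shift, interpolation)
    out.meta["motion_corrected"] = True
    return out


def inject_motion(scan: RawScan, motion: MotionGraph,
                  interpolation: str = "fourier") -> RawScan:
    """Corrupt a clean scan by shifting each A-line by ``+motion``."""
    if len(motion) != scan.config.n_alines:
        raise CorrectionError(
            f"motion length {len(motion)} != number of A-lines {scan.config.n_alines}")
    shift = -motion.displacement / scan.config.dz
    out = _shift_alines(scan, shift, interpolation)
    out.meta["motion_injected"] = True
    return out


def retrieve_and_correct(scan: RawScan, depth_gate: tuple | None = None,
                         min_snr_db: float = 10.0,
                         median_window: tuple = DEFAULT_MEDIAN_WINDOW,
                         gaussian_sigma: tuple = DEFAULT_GAUSSIAN_SIGMA,
                         interpolation: str = "fourier"):
    """Full surface-based correction chain.

    Runs ``extract_surface -> smooth_surface -> motion_graph ->
    correct_scan`` and returns ``(corrected_scan, retrieved_motion)``.
    """
    s_d = extract_surface(scan, depth_gate=depth_gate, min_snr_db=min_snr_db)
    s_c = smooth_surface(s_d, median_window=median_window,
                         gaussian_sigma=gaussian_sigma)
    retrieved = motion_graph(s_d, s_c, dt=1.0 / scan.config.pulse_rate,
                             order=scan.acquisition_order)
    corrected = correct_scan(scan, retrieved, interpolation=interpolation)
    return corrected, retrieved


def point_displacement(scan: RawScan, max_lag: int = 150) -> MotionGraph:
    """Vertical displacement of a fixed-head point measurement.

    Each repeated A-line is cross-correlated with the first shot; the lag
    maximizing the normalized cross-correlation, refined by parabolic
    interpolation, is converted to um via the depth-per-sample.  Positive
    displacement means the absorber moved deeper.  ``displacement[0]`` is
    exactly zero.  The searchable lag defaults to +-150 samples (+-225 um
    with the default geometry).
    """
    if scan.kind is not ScanKind.POINT:
        raise CorrectionError("point_displacement requires a point measurement scan")
    lines = scan.alines().astype(float)
    n_lines, n = lines.shape
    if n_lines < 2:
        raise CorrectionError("need at least two repeated A-lines")
    ref = lines[0]
    ref_norm = float(np.linalg.norm(ref))
    if ref_norm == 0.0:
        raise CorrectionError("reference A-line is all zeros")
    max_lag = int(min(max_lag, n - 1))
    # full cross-correlation via FFT; lag l lives at index (n - 1) + l
    corr = fftconvolve(lines, ref[::-1][None, :], mode="full", axes=1)
    norms = np.linalg.norm(lines, axis=1)
    norms[norms == 0] = 1.0
    corr /= (norms[:, None] * ref_norm)
    center = n - 1
    window = corr[:, center - max_lag:center + max_lag + 1]
    idx = np.argmax(window, axis=1)
    lag = idx.astype(float) - max_lag
    interior = (idx > 0) & (idx < 2 * max_lag)
    for i in np.flatnonzero(interior):
        y0, y1, y2 = window[i, idx[i] - 1:idx[i] + 2]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            lag[i] += float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    disp = lag * scan.config.dz
    disp[0] = 0.0
    return MotionGraph(displacement=disp, dt=1.0 / scan.config.pulse_rate)
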