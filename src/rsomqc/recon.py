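"""Simplified dual-band delay-and-sum reconstruction and CNR scoring.

A textbook delay-and-sum beamformer with Hann apodization inside an
aperture cone stands in for the (external) system reconstruction, so that
the contrast-to-noise ratio of corrected versus corrupted synthetic scans
can be compared.  Images are rendered as maximum intensity projections of
the envelope volume; the two conventional frequency bands (10-40 MHz for
larger structures, 40-120 MHz for smaller ones) are obtained with a
zero-phase Butterworth band-pass.

All CNR-based decisions in this package are relative (dB drops against a
reference reconstruction), never absolute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .data_model import DataValidationError, RawScan, RsomQCError

__all__ = ["ReconError", "ReconGrid", "CnrResult", "bandpass",
           "default_grid", "reconstruct_das", "mip", "compute_cnr"]

_AXIS_BY_NAME = {"fast": 0, "slow": 1, "depth": 2}


class ReconError(RsomQCError, ValueError):
    pass


@dataclass(frozen=True)
class ReconGrid:
    """Voxel centre coordinates of the reconstruction volume, um."""

    x: np.ndarray  # fast axis
    y: np.ndarray  # slow axis
    z: np.ndarray  # depth

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.ndim != 1 or v.size < 1:
                raise ReconError(f"grid axis {name} must be a non-empty 1-D array")

    @property
    def shape(self) -> tuple:
        return (self.x.size, self.y.size, self.z.size)


@dataclass(frozen=True)
class CnrResult:
    """Contrast-to-noise ratio: peak feature intensity over background std."""

    ip: float
    sb: float
    cnr_db: float
    log_factor: float = 20.0  # dB convention: 20 = amplitude, 10 = power

    def __post_init__(self) -> None:
        if not (self.ip > 0 and self.sb > 0):
            raise DataValidationError("ip and sb must be > 0")
        expected = self.log_factor * math.log10(self.ip / self.sb)
        if not np.isclose(self.cnr_db, expected, rtol=1e-9, atol=1e-9):
            raise DataValidationError("cnr_db != log_factor*log10(ip/sb)")


def bandpass(scan: RawScan, low: float, high: float, order: int = 4) -> RawScan:
    """Zero-phase Butterworth band-pass along the depth axis of every A-line."""
    nyq = scan.config.sampling_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ReconError("band must satisfy 0 < low < high < Nyquist")
    sos = butter(order, [low, high], btype="band", fs=scan.config.sampling_rate,
                 output="sos")
    filtered = sosfiltfilt(sos, scan.amplitudes.astype(float), axis=-1)
    return RawScan(amplitudes=filtered.astype(np.float32), config=scan.config,
                   kind=scan.kind, acquisition_order=scan.acquisition_order,
                   meta={**scan.meta, "band_hz": (float(low), float(high))})


def default_grid(scan: RawScan, z_range: tuple | None = None,
                 z_step: float | None = None) -> ReconGrid:
    """Grid aligned with the scan positions; depth voxels default to 2 * dz."""
    cfg = scan.config
    x = np.arange(cfg.n_fast) * cfg.step_fast
    y = np.arange(cfg.n_slow) * cfg.step_slow
    if z_step is None:
        z_step = 2.0 * cfg.dz
    if z_range is None:
        z_range = (z_step, scan.depth_window)
    z = np.arange(z_range[0], z_range[1] + 1e-9, z_step)
    if z.size == 0:
        raise ReconError("empty depth range")
    return ReconGrid(x=x, y=y, z=z)


def reconstruct_das(scan: RawScan, grid: ReconGrid | None = None,
                    half_angle_deg: float = 25.0,
                    envelope: bool = True) -> np.ndarray:
    """Delay-and-sum reconstruction onto ``grid``.

    Each voxel sums the A-line amplitudes at the one-way time-of-flight
    from the voxel to every scan position inside an aperture cone of
    ``half_angle_deg``, Hann-apodized across the aperture.  The returned
    volume is the magnitude of the analytic signal along depth (set
    ``envelope=False`` for the raw sum).
    """
    if grid is None:
        grid = default_grid(scan)
    cfg = scan.config
    dz = cfg.dz
    n = scan.n_samples
    tan_a = math.tan(math.radians(half_angle_deg))
    gx, gy, gz = grid.x, grid.y, grid.z
    if gz.min() <= 0:
        raise ReconError("grid depths must be > 0")
    rho_max_per_z = gz * tan_a
    rho_max = float(rho_max_per_z.max())

    vol = np.zeros(grid.shape)
    wsum = np.zeros(grid.shape)
    amp = scan.amplitudes.astype(float)
    xs = np.arange(cfg.n_fast) * cfg.step_fast
    ys = np.arange(cfg.n_slow) * cfg.step_slow

    for i in range(cfg.n_fast):
        dx = gx - xs[i]
        xsel = np.abs(dx) <= rho_max
        if not xsel.any():
            continue
        dx2 = dx[xsel] ** 2
        for j in range(cfg.n_slow):
            dy = gy - ys[j]
            ysel = np.abs(dy) <= rho_max
            if not ysel.any():
                continue
            rho2 = dx2[:, None] + dy[ysel][None, :] ** 2  # [nx, ny]
            rho = np.sqrt(rho2)
            # aperture cone: lateral distance <= z * tan(half_angle)
            inside = rho[:, :, None] <= rho_max_per_z[None, None, :]
            if not inside.any():
                continue
            r = np.sqrt(rho2[:, :, None] + gz[None, None, :] ** 2)
            idx = r / dz
            i0 = np.clip(idx.astype(np.int64), 0, n - 2)
            frac = idx - i0
            aline = amp[i, j]
            samp = aline[i0] * (1.0 - frac) + aline[i0 + 1] * frac
            samp[idx > n - 1] = 0.0  # time-of-flight beyond the record
            # Hann apodization across the aperture
            with np.errstate(invalid="ignore", divide="ignore"):
                u = rho[:, :, None] / rho_max_per_z[None, None, :]
            w = np.where(inside, np.cos(0.5 * np.pi * np.clip(u, 0.0, 1.0)) ** 2, 0.0)
            ii = np.ix_(np.flatnonzero(xsel), np.flatnonzero(ysel), np.arange(gz.size))
            vol[ii] += w * samp
            wsum[ii] += w
    if (wsum == 0).any():
        raise ReconError("empty aperture for at least one voxel; widen the grid "
                         "or the aperture angle")
    if envelope:
        vol = np.abs(hilbert(vol, axis=-1))
    return vol


def mip(volume: np.ndarray, axis: str = "depth") -> np.ndarray:
    """Maximum intensity projection along ``fast``, ``slow`` or ``depth``."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ReconError("mip expects a 3-D volume")
    if axis not in _AXIS_BY_NAME:
        raise ReconError(f"unknown axis {axis!r}; expected one of {sorted(_AXIS_BY_NAME)}")
    return volume.max(axis=_AXIS_BY_NAME[axis])


def compute_cnr(image: np.ndarray, feature_roi: tuple,
                background_roi: tuple, log_factor: float = 20.0) -> CnrResult:
    """CNR of a 2-D image: peak over ``feature_roi`` / std over background.

    ROIs are ``(row0, row1, col0, col1)`` pixel rectangles; they must be
    disjoint and the background must hold at least 64 pixels.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ReconError("compute_cnr expects a 2-D image")

    def _rect(roi):
        r0, r1, c0, c1 = (int(v) for v in roi)
        if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
            raise ReconError(f"ROI {roi} outside the image")
        return r0, r1, c0, c1

    fr = _rect(feature_roi)
    br = _rect(background_roi)
    rows_disjoint = fr[1] <= br[0] or br[1] <= fr[0]
    cols_disjoint = fr[3] <= br[2] or br[3] <= fr[2]
    if not (rows_disjoint or cols_disjoint):
        raise ReconError("feature and background ROIs overlap")
    if (br[1] - br[0]) * (br[3] - br[2]) < 64:
        raise ReconError("background ROI must hold at least 64 pixels")
    ip = float(image[fr[0]:fr[1], fr[2]:fr[3]].max())
    sb = float(image[br[0]:br[1], br[2]:br[3]].std())
    if sb == 0.0:
        raise ReconError("background ROI has zero standard deviation")
    if ip <= 0.0:
        raise ReconError("feature ROI peak must be > 0")
    cnr_db = log_factor * math.log10(ip / sb)
    return CnrResult(ip=ip, sb=sb, cnr_db=cnr_db, log_factor=log_factor)
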