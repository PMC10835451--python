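"""Suture-reference SNR measurement and scan gating.

A reference scan of a 100 um suture attached to the coupling membrane is
measured before every full scan.  The SNR is the ratio between the peak
signal intensity and the standard deviation of the noise background,
expressed in dB with the amplitude convention ``20 * log10``.  A full scan
is allowed only when the suture SNR reaches the reference value
``r_snr`` established at the focal position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .data_model import DataValidationError, RawScan, RsomQCError

__all__ = ["SnrError", "SnrMeasurement", "GateDecision",
           "compute_snr", "find_focus_offset", "reference_gate"]

#: fraction of the deepest samples used as the default noise window
DEFAULT_NOISE_FRACTION = 0.2


class SnrError(RsomQCError, ValueError):
    pass


@dataclass(frozen=True)
class SnrMeasurement:
    snr_db: float
    peak_amplitude: float
    noise_std: float
    signal_window: tuple  # (start, stop) sample range
    noise_window: tuple
    log_factor: float = 20.0  # dB convention: 20 = amplitude, 10 = power

    def __post_init__(self) -> None:
        expected = self.log_factor * np.log10(self.peak_amplitude / self.noise_std)
        if not np.isclose(self.snr_db, expected, rtol=1e-9, atol=1e-9):
            raise DataValidationError("snr_db != 20*log10(peak/noise_std)")
        s0, s1 = self.signal_window
        n0, n1 = self.noise_window
        if not (s1 <= n0 or n1 <= s0):
            raise DataValidationError("signal and noise windows overlap")


@dataclass(frozen=True)
class GateDecision:
    passed: bool
    snr_db: float
    r_snr: float
    message: str


def _resolve_windows(scan: RawScan, signal_window, noise_window):
    n = scan.n_samples
    if noise_window is None:
        noise_window = (int(round((1.0 - DEFAULT_NOISE_FRACTION) * n)), n)
    n0, n1 = int(noise_window[0]), int(noise_window[1])
    if signal_window is None:
        signal_window = (0, n0)
    s0, s1 = int(signal_window[0]), int(signal_window[1])
    if not (0 <= s0 < s1 <= n and 0 <= n0 < n1 <= n):
        raise SnrError("windows must be non-empty and inside the recorded depth range")
    if not (s1 <= n0 or n1 <= s0):
        raise SnrError("signal and noise windows must be disjoint")
    if (n1 - n0) * scan.config.n_alines < 16:
        raise SnrError("noise window too small (need >= 16 pooled samples)")
    return (s0, s1), (n0, n1)


def compute_snr(scan: RawScan, signal_window: tuple | None = None,
                noise_window: tuple | None = None,
                mode: str = "coherent", log_factor: float = 20.0) -> SnrMeasurement:
    """Measure the suture SNR of a reference scan.

    ``mode="coherent"`` (default) averages the A-lines coherently and takes
    the peak of the envelope of the mean trace, which keeps the peak
    estimate unbiased down to low SNR.  ``mode="peak"`` takes the maximum
    absolute amplitude over all A-lines in the signal window.  The noise
    level is always the standard deviation of the raw amplitudes pooled
    over the noise window.

    Defaults: noise window = deepest 20 % of samples, signal window =
    everything above it.  ``log_factor`` selects the dB convention
    (20 = amplitude, 10 = power).
    """
    (s0, s1), (n0, n1) = _resolve_windows(scan, signal_window, noise_window)
    lines = scan.amplitudes.reshape(-1, scan.n_samples)
    noise = lines[:, n0:n1]
    noise_std = float(noise.std())
    if noise_std == 0.0:
        raise SnrError("noise window has zero standard deviation")
    if mode == "coherent":
        mean_line = lines.mean(axis=0)
        envelope = np.abs(hilbert(mean_line))
        peak = float(envelope[s0:s1].max())
    elif mode == "peak":
        peak = float(np.abs(lines[:, s0:s1]).max())
    else:
        raise SnrError(f"unknown mode {mode!r}")
    if peak <= 0.0:
        raise SnrError("no signal in the signal window")
    snr_db = log_factor * float(np.log10(peak / noise_std))
    return SnrMeasurement(snr_db=snr_db, peak_amplitude=peak, noise_std=noise_std,
                          signal_window=(s0, s1), noise_window=(n0, n1),
                          log_factor=log_factor)


def find_focus_offset(scans: Sequence[tuple], **snr_kwargs):
    """Select the head-to-skin offset with the maximal suture SNR.

    ``scans`` is a sequence of ``(offset_um, RawScan)``.  Returns
    ``(offset, SnrMeasurement)`` of the maximum; ties break toward the
    smaller offset.  The winning SNR is the natural reference value
    ``r_snr`` for subsequent gating.
    """
    if len(scans) == 0:
        raise SnrError("need at least one (offset, scan) pair")
    best = None
    for offset, scan in sorted(scans, key=lambda p: p[0]):
        m = compute_snr(scan, **snr_kwargs)
        if best is None or m.snr_db > best[1].snr_db:
            best = (offset, m)
    return best


def reference_gate(measurement: SnrMeasurement, r_snr: float) -> GateDecision:
    """Pass iff the measured suture SNR reaches the reference value."""
    passed = measurement.snr_db >= r_snr
    if passed:
        msg = (f"suture SNR {measurement.snr_db:.2f} dB >= reference "
               f"{r_snr:.2f} dB: full scan may begin")
    else:
        msg = (f"suture SNR {measurement.snr_db:.2f} dB below reference "
               f"{r_snr:.2f} dB: check the laser energy and the coupling "
               "between the device and the tissue before scanning")
    return GateDecision(passed=passed, snr_db=measurement.snr_db, r_snr=r_snr,
                        message=msg)
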