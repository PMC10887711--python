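"""Sensor-space preprocessing and the desynchronization index.

Implements the standard event-related desynchronization (ERD) pipeline:
average re-referencing, trimming of attention transients at block edges,
trial epoching, band-power estimation, a simple amplitude-based artifact
rejector, and the classic percent-change desynchronization index
(positive = suppression relative to the reference interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import BandDefinition, MultichannelSeries

__all__ = [
    "DesyncIndex",
    "average_rereference",
    "trim_block",
    "epoch_trials",
    "band_power",
    "desync_index",
    "reject_artifacts",
    "RejectionReport",
    "DEFAULT_EPOCH_WINDOW",
    "DEFAULT_REFERENCE_WINDOW",
    "DEFAULT_ACTIVE_WINDOW",
]

logger = logging.getLogger(__name__)

#: Trial epoch extent relative to onset (s): covers both sub-windows below.
DEFAULT_EPOCH_WINDOW = (-1.5, 3.5)
#: Pre-stimulus reference interval for the desynchronization index (s).
DEFAULT_REFERENCE_WINDOW = (-0.5, 0.0)
#: Active interval for the desynchronization index (s).
DEFAULT_ACTIVE_WINDOW = (0.5, 2.5)


@dataclass(frozen=True)
class DesyncIndex:
    """Percent band-power change of an active window vs a reference window."""

    band: BandDefinition
    value: float
    reference_window: tuple[float, float]
    active_window: tuple[float, float]


def average_rereference(series: MultichannelSeries) -> MultichannelSeries:
    """Subtract the instantaneous channel mean (common-average reference)."""
    if series.n_channels < 2:
        raise ValueError("average re-referencing needs at least 2 channels")
    data = series.data - series.data.mean(axis=0, keepdims=True)
    return MultichannelSeries(data, series.rate, list(series.labels), series.t0)


def trim_block(
    series: MultichannelSeries,
    block_len: float = 80.0,
    trim: float = 10.0,
) -> MultichannelSeries:
    """Cut ``trim`` seconds from each end of a ``block_len``-second block.

    The default (80 s block, 10 s trim) yields the central 60 s segment,
    removing attention transients tied to stimulus onset and offset.
    """
    if trim < 0:
        raise ValueError("trim must be non-negative")
    if trim >= block_len / 2:
        raise ValueError(f"trim={trim} s >= half the block length {block_len} s")
    if series.duration + 0.5 / series.rate < block_len:
        raise ValueError(
            f"series of {series.duration:.3f} s is shorter than the "
            f"{block_len} s block"
        )
    i0 = int(round(trim * series.rate))
    n_keep = int(round((block_len - 2 * trim) * series.rate))
    data = series.data[:, i0 : i0 + n_keep]
    return MultichannelSeries(
        data, series.rate, list(series.labels), series.t0 + trim
    )


def epoch_trials(
    series: MultichannelSeries,
    onsets: np.ndarray,
    window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
) -> tuple[list[MultichannelSeries], int]:
    """Cut fixed-length epochs around trial onsets.

    ``window`` is (start, end) in seconds relative to each onset; epochs
    whose window falls outside the series are skipped with a warning.
    Returns the epochs (``t0`` set to the window start relative to
    onset) and the number of skipped onsets.
    """
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("epoch window must have positive length")
    n_win = int(round((w1 - w0) * series.rate))
    epochs: list[MultichannelSeries] = []
    skipped = 0
    for onset in np.atleast_1d(np.asarray(onsets, dtype=float)):
        i0 = int(round((onset + w0 - series.t0) * series.rate))
        if i0 < 0 or i0 + n_win > series.n_samples:
            skipped += 1
            logger.warning(
                "onset at %.3f s: epoch window [%.3f, %.3f] s outside series; skipped",
                onset, onset + w0, onset + w1,
            )
            continue
        epochs.append(
            MultichannelSeries(
                series.data[:, i0 : i0 + n_win].copy(),
                series.rate,
                list(series.labels),
                t0=w0,
            )
        )
    return epochs, skipped


def band_power(
    series: MultichannelSeries,
    band: BandDefinition,
    window: tuple[float, float] | None = None,
    method: str = "welch",
) -> np.ndarray:
    """Mean band-limited power per channel over a time window.

    ``method="welch"`` (default) integrates the Welch PSD (Hann window,
    1 s segments, 50% overlap) over ``[f_lo, f_hi]``; ``method="hilbert"``
    band-passes (4th-order Butterworth) and averages the squared analytic
    amplitude / 2, which equals mean squared signal power for narrowband
    signals.  Both return non-negative power in (input units)^2.
    """
    band.check_nyquist(series.rate)
    seg = series if window is None else series.crop(*window)
    if seg.n_samples < 8:
        raise ValueError("window too short for power estimation")
    if method == "welch":
        nper = min(int(series.rate), seg.n_samples)
        freqs, psd = signal.welch(
            seg.data, fs=series.rate, window="hann", nperseg=nper,
            noverlap=nper // 2, axis=-1,
        )
        mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
        if not mask.any():
            raise ValueError("no PSD bins inside band; window too short")
        return np.trapezoid(psd[:, mask], freqs[mask], axis=-1)
    elif method == "hilbert":
        sos = signal.butter(
            4, [band.f_lo, band.f_hi], btype="bandpass", fs=series.rate,
            output="sos",
        )
        filt = signal.sosfiltfilt(sos, seg.data, axis=-1)
        env = np.abs(signal.hilbert(filt, axis=-1))
        return (env**2).mean(axis=-1) / 2.0
    raise ValueError(f"unknown band_power method {method!r}")


def desync_index(
    p_active: float | np.ndarray,
    p_reference: float | np.ndarray,
    band: BandDefinition | None = None,
    reference_window: tuple[float, float] = DEFAULT_REFERENCE_WINDOW,
    active_window: tuple[float, float] = DEFAULT_ACTIVE_WINDOW,
) -> DesyncIndex:
    """Percent power change between active and reference windows.

    ``value = (p_reference - p_active) / p_reference * 100``; positive
    values mean desynchronization (power suppression during the active
    window), negative values synchronization.
    """
    p_active = float(np.mean(p_active))
    p_reference = float(np.mean(p_reference))
    if p_reference <= 0:
        raise ValueError("reference power must be positive")
    value = (p_reference - p_active) / p_reference * 100.0
    return DesyncIndex(
        band=band, value=value,
        reference_window=reference_window, active_window=active_window,
    )


@dataclass
class RejectionReport:
    """Outcome of artifact rejection: which epochs were dropped and why."""

    dropped: list[int]
    reasons: list[str]
    z_threshold: float
    n_input: int

    @property
    def n_kept(self) -> int:
        return self.n_input - len(self.dropped)


def reject_artifacts(
    epochs: list[MultichannelSeries],
    z_threshold: float = 5.0,
) -> tuple[list[MultichannelSeries], RejectionReport]:
    """Drop epochs with outlying peak amplitudes.

    For each channel, the peak absolute amplitude per epoch is z-scored
    across epochs; an epoch whose worst channel exceeds ``z_threshold``
    is rejected.  A simple, transparent stand-in for template-based
    artifact removal.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    peaks = np.array([np.abs(e.data).max(axis=1) for e in epochs])  # (n_ep, n_ch)
    mu = peaks.mean(axis=0)
    sd = peaks.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, np.inf)  # constant channel -> never rejects
    z = (peaks - mu) / sd
    dropped, reasons = [], []
    for i in range(len(epochs)):
        worst = int(np.argmax(z[i]))
        if z[i, worst] > z_threshold:
            dropped.append(i)
            reasons.append(
                f"channel {epochs[i].labels[worst]} peak z={z[i, worst]:.2f} "
                f"> {z_threshold}"
            )
    kept = [e for i, e in enumerate(epochs) if i not in set(dropped)]
    if not kept:
        raise ValueError(
            "all epochs rejected; review z_threshold "
            f"(currently {z_threshold})"
        )
    return kept, RejectionReport(dropped, reasons, z_threshold, len(epochs))
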