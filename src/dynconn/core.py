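"""Core data containers shared across the pipeline.

The unit of all signal processing is :class:`MultichannelSeries` — a
(channels x samples) array with a sampling rate and channel labels, the
in-memory twin of a continuous EEG recording or a set of extracted source
signals.  Frequency bands are carried as :class:`BandDefinition`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MultichannelSeries",
    "BandDefinition",
    "MU_BAND",
    "BETA_BAND",
]


@dataclass
class MultichannelSeries:
    """A regularly sampled multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values in microvolts (sensor space) or arbitrary units
        (source space).
    rate : float
        Sampling rate in Hz.
    labels : sequence of str, optional
        One name per channel; defaults to ``ch0, ch1, ...``.
    t0 : float
        Time of the first sample in seconds (e.g. relative to a trial
        onset for epochs).
    """

    data: np.ndarray
    rate: float
    labels: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.data.shape[0])]
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the series in seconds."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (``t0`` + n/rate)."""
        return self.t0 + np.arange(self.n_samples) / self.rate

    def copy(self) -> "MultichannelSeries":
        return replace(self, data=self.data.copy(), labels=list(self.labels))

    # -- slicing --------------------------------------------------------
    def crop(self, start: float, end: float) -> "MultichannelSeries":
        """Return the sub-series for absolute times ``[start, end)`` seconds."""
        i0 = int(round((start - self.t0) * self.rate))
        i1 = int(round((end - self.t0) * self.rate))
        if i0 < 0 or i1 > self.n_samples or i0 >= i1:
            raise ValueError(
                f"window [{start}, {end}) s outside series "
                f"[{self.t0}, {self.t0 + self.duration}) s"
            )
        return MultichannelSeries(
            self.data[:, i0:i1], self.rate, list(self.labels), t0=start
        )

    def pick(self, indices: Sequence[int]) -> "MultichannelSeries":
        idx = list(indices)
        return MultichannelSeries(
            self.data[idx], self.rate, [self.labels[i] for i in idx], t0=self.t0
        )


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[f_lo, f_hi]`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo

    def contains(self, f: float) -> bool:
        return self.f_lo <= f <= self.f_hi

    def check_nyquist(self, rate: float) -> None:
        if self.f_hi >= rate / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.f_hi} Hz is not below "
                f"Nyquist ({rate / 2} Hz)"
            )


#: Sensorimotor mu rhythm, 8-12 Hz.
MU_BAND = BandDefinition("mu", 8.0, 12.0)
#: Low beta, 13-20 Hz.
BETA_BAND = BandDefinition("beta", 13.0, 20.0)
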