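"""Frequency-domain coherent-source estimation (DICS beamforming).

Dynamic Imaging of Coherent Sources derives, for every candidate source
location, a spatial filter from the sensor cross-spectral density (CSD)
and the lead field, and from it band-limited source power and coherence
maps.  The estimator follows the statsmodels convention: :class:`DICS`
is the model (lead field + CSD + regularization), ``fit()`` returns a
:class:`DICSResults` carrying the filters and the derived maps.

For source column :math:`L_s` and band-averaged real CSD
:math:`C_r = \\mathrm{Re}(C) + \\lambda\\,\\overline{\\mathrm{diag}}\\,I`,
the filter is :math:`w_s = (L_s^T C_r^{-1} L_s)^{-1} L_s^T C_r^{-1}`,
which satisfies the unit-gain constraint :math:`w_s L_s = 1`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .core import BandDefinition, MultichannelSeries

__all__ = [
    "LeadField",
    "CSDMatrix",
    "CoherentSource",
    "PooledSourceSignal",
    "DICS",
    "DICSResults",
    "compute_csd",
    "pool_source_signal",
    "source_significance",
    "SignificanceResult",
    "toy_grid",
    "make_toy_leadfield",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class LeadField:
    """Fixed-orientation gain matrix from sources to sensors.

    ``gain`` has shape (n_sensors, n_sources); coordinates are mm
    triples.  ``head_model`` is a free-text provenance tag.
    """

    gain: np.ndarray
    sensor_coords: np.ndarray
    source_coords: np.ndarray
    head_model: str = "user-supplied"

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.sensor_coords = np.asarray(self.sensor_coords, dtype=float)
        self.source_coords = np.asarray(self.source_coords, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be a 2-D (sensors x sources) matrix")
        if not np.isfinite(self.gain).all():
            raise ValueError("gain must be finite")
        ns, nq = self.gain.shape
        if self.sensor_coords.shape != (ns, 3):
            raise ValueError(f"sensor_coords must be ({ns}, 3)")
        if self.source_coords.shape != (nq, 3):
            raise ValueError(f"source_coords must be ({nq}, 3)")
        norms = np.linalg.norm(self.gain, axis=0)
        if (norms == 0).any():
            raise ValueError("lead field contains an all-zero source column")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class CSDMatrix:
    """Sensor cross-spectral density per frequency bin.

    ``values`` has shape (n_freqs, n_sensors, n_sensors), Hermitian in
    the last two axes with real non-negative diagonal.
    """

    values: np.ndarray
    freqs: np.ndarray
    n_segments: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must be (n_freqs, n, n)")
        if len(self.freqs) != self.values.shape[0]:
            raise ValueError("freqs length must match values")
        herm_dev = np.abs(
            self.values - self.values.conj().transpose(0, 2, 1)
        ).max()
        if herm_dev > 1e-10 * max(1.0, np.abs(self.values).max()):
            raise ValueError(f"CSD not Hermitian (max deviation {herm_dev:.3g})")

    @property
    def n_sensors(self) -> int:
        return self.values.shape[1]

    def band_mean(self) -> np.ndarray:
        """CSD averaged over the stored frequency bins."""
        return self.values.mean(axis=0)


@dataclass(frozen=True)
class CoherentSource:
    """A localized band-specific generator."""

    grid_index: int
    coord: tuple[float, float, float]
    band: BandDefinition
    power: float
    coherence: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.coherence is not None and not 0 <= self.coherence <= 1 + 1e-9:
            raise ValueError("coherence must lie in [0, 1]")
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class PooledSourceSignal:
    """Band-power-weighted combination of voxel series into one signal."""

    source_id: str
    series: MultichannelSeries
    weights: np.ndarray


# ---------------------------------------------------------------------------
# CSD estimation
# ---------------------------------------------------------------------------

def compute_csd(
    series: MultichannelSeries,
    band: BandDefinition,
    segment_len: float = 1.0,
) -> CSDMatrix:
    """Welch-averaged cross-spectral density over a band.

    Cross-spectra are estimated with Hann-windowed segments of
    ``segment_len`` seconds and 50% overlap; only bins inside
    ``[f_lo, f_hi]`` are retained.
    """
    band.check_nyquist(series.rate)
    nper = int(round(segment_len * series.rate))
    if series.n_samples < nper:
        raise ValueError(
            f"series of {series.n_samples} samples shorter than one "
            f"{nper}-sample spectral segment"
        )
    x = series.data
    freqs, Sxy = signal.csd(
        x[:, np.newaxis, :], x[np.newaxis, :, :],
        fs=series.rate, window="hann", nperseg=nper, noverlap=nper // 2,
        axis=-1,
    )
    mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    if not mask.any():
        raise ValueError("no frequency bins inside the band")
    values = Sxy[:, :, mask].transpose(2, 0, 1)
    # enforce exact Hermitian symmetry against floating-point asymmetry
    values = 0.5 * (values + values.conj().transpose(0, 2, 1))
    n_segments = max(1, (series.n_samples - nper) // (nper // 2) + 1)
    return CSDMatrix(values, freqs[mask], n_segments)


# ---------------------------------------------------------------------------
# The DICS model
# ---------------------------------------------------------------------------

class DICS:
    """DICS beamformer model for one frequency band.

    Parameters
    ----------
    csd : CSDMatrix
        Band-limited sensor cross-spectral density.
    leadfield : LeadField
        Forward gain matrix; sensor count must match the CSD.
    regularization : float
        Tikhonov loading as a fraction of the mean sensor power
        (mean of the real CSD diagonal); default 5%.
    """

    def __init__(
        self,
        csd: CSDMatrix,
        leadfield: LeadField,
        regularization: float = 0.05,
    ) -> None:
        if leadfield.n_sensors != csd.n_sensors:
            raise ValueError(
                f"lead field has {leadfield.n_sensors} sensors, CSD has "
                f"{csd.n_sensors}"
            )
        if regularization < 0:
            raise ValueError("regularization must be non-negative")
        self.csd = csd
        self.leadfield = leadfield
        self.regularization = regularization

    def fit(self) -> "DICSResults":
        """Compute the per-source spatial filters."""
        C = self.csd.band_mean()
        Cr = np.real(C).copy()
        loading = self.regularization * np.mean(np.diag(Cr))
        Cr[np.diag_indices_from(Cr)] += loading
        try:
            Cinv = np.linalg.inv(Cr)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "regularized CSD is singular; increase `regularization`"
            ) from err
        L = self.leadfield.gain
        CiL = Cinv @ L                     # (n_sensors, n_sources)
        denom = np.einsum("ks,ks->s", L, CiL)
        if np.any(denom <= 0):
            raise np.linalg.LinAlgError(
                "non-positive filter normalization; regularized CSD is "
                "numerically singular — increase `regularization`"
            )
        filters = (CiL / denom).T          # (n_sources, n_sensors)
        return DICSResults(self, filters)


class DICSResults:
    """Fitted DICS filters and the maps derived from them."""

    def __init__(self, model: DICS, filters: np.ndarray) -> None:
        self.model = model
        self.filters = filters  # (n_sources, n_sensors)

    # -- maps -----------------------------------------------------------
    def power_map(self, csd: CSDMatrix | None = None) -> np.ndarray:
        """Band source power ``Re(w C w^H)`` per grid point (non-negative)."""
        C = (csd or self.model.csd).band_mean()
        W = self.filters
        power = np.real(np.einsum("sk,kl,sl->s", W, C, W.conj()))
        return np.maximum(power, 0.0)

    def source_csd(self, a: int, b: int) -> np.ndarray:
        """Cross-spectrum between source estimates ``a`` and ``b`` per bin."""
        wa, wb = self.filters[a], self.filters[b]
        return np.einsum("k,fkl,l->f", wa, self.model.csd.values, wb.conj())

    def coherence_map(self, reference: int | np.ndarray) -> np.ndarray:
        """Magnitude-squared coherence of every source with a reference.

        ``reference`` is a source grid index, or a weight vector over
        sensors (e.g. a one-hot vector for a single sensor).
        """
        V = self.model.csd.values  # (F, n, n)
        W = self.filters
        w_ref = W[reference] if isinstance(reference, (int, np.integer)) else \
            np.asarray(reference, dtype=float)
        S_rr = np.real(np.einsum("k,fkl,l->f", w_ref, V, w_ref.conj()))
        if np.all(S_rr <= 0):
            raise ValueError("reference signal has zero band power")
        S_sr = np.einsum("sk,fkl,l->sf", W, V, w_ref.conj())
        S_ss = np.real(np.einsum("sk,fkl,sl->sf", W, V, W.conj()))
        with np.errstate(divide="ignore", invalid="ignore"):
            coh = np.abs(S_sr) ** 2 / (S_ss * S_rr[np.newaxis, :])
        coh = np.nan_to_num(coh, nan=0.0)
        return np.clip(coh.mean(axis=1), 0.0, 1.0)

    # -- source series --------------------------------------------------
    def extract_source_series(
        self, series: MultichannelSeries, indices: Sequence[int] | None = None
    ) -> MultichannelSeries:
        """Project sensor data through the filters: one channel per source."""
        if series.n_channels != self.model.leadfield.n_sensors:
            raise ValueError("sensor count mismatch with lead field")
        W = self.filters if indices is None else self.filters[list(indices)]
        labels = [
            f"src{i}" for i in (indices if indices is not None
                                else range(W.shape[0]))
        ]
        return MultichannelSeries(W @ series.data, series.rate, labels, series.t0)

    def summary(self, top: int = 10) -> pd.DataFrame:
        """Table of the strongest grid points by band power."""
        power = self.power_map()
        order = np.argsort(power)[::-1][:top]
        coords = self.model.leadfield.source_coords[order]
        return pd.DataFrame(
            {
                "grid_index": order,
                "x_mm": coords[:, 0],
                "y_mm": coords[:, 1],
                "z_mm": coords[:, 2],
                "power": power[order],
            }
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Pooling and significance
# ---------------------------------------------------------------------------

def pool_source_signal(
    voxel_series: MultichannelSeries,
    band: BandDefinition,
    source_id: str = "pooled",
) -> PooledSourceSignal:
    """Combine voxel series into one pooled source signal.

    Weights are proportional to each voxel's band power (its second-order
    spectrum integrated over the band) and normalized to sum to one.
    """
    from .preprocess import band_power

    if voxel_series.n_channels < 1:
        raise ValueError("need at least one voxel series")
    powers = band_power(voxel_series, band)
    total = powers.sum()
    if total <= 0:
        raise ValueError("all voxel series have zero band power")
    weights = powers / total
    pooled = weights @ voxel_series.data
    return PooledSourceSignal(
        source_id=source_id,
        series=MultichannelSeries(
            pooled[np.newaxis, :], voxel_series.rate, [source_id],
            voxel_series.t0,
        ),
        weights=weights,
    )


@dataclass
class SignificanceResult:
    """Permutation-test outcome for one source statistic."""

    p_value: float
    observed: float
    perm_values: np.ndarray = field(repr=False)
    significant: bool = False


def source_significance(
    statistic: Callable[[MultichannelSeries], float],
    series: MultichannelSeries,
    n_perm: int = 100,
    seed: int = 0,
    segment_len: float = 1.0,
    criterion: float = 0.01,
) -> SignificanceResult:
    """Monte-Carlo segment-shuffling significance of a source statistic.

    The series is cut into non-overlapping ``segment_len``-second
    segments whose order is randomly permuted ``n_perm`` times; the
    statistic is recomputed on each surrogate.  The add-one permutation
    p-value is ``(1 + #{perm >= observed}) / (1 + n_perm)``; the source
    is called significant when the observed value exceeds the
    ``1 - criterion`` quantile of the surrogate distribution (the 99th
    percentile by default).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seg = int(round(segment_len * series.rate))
    n_seg = series.n_samples // seg
    if n_seg < 2:
        raise ValueError("series must contain at least 2 shuffling segments")
    rng = np.random.default_rng(seed)
    observed = float(statistic(series))
    blocks = series.data[:, : n_seg * seg].reshape(
        series.n_channels, n_seg, seg
    )
    perm_values = np.empty(n_perm)
    for k in range(n_perm):
        order = rng.permutation(n_seg)
        shuffled = blocks[:, order, :].reshape(series.n_channels, n_seg * seg)
        perm_values[k] = statistic(
            MultichannelSeries(shuffled, series.rate, list(series.labels))
        )
    p = (1 + int(np.sum(perm_values >= observed))) / (1 + n_perm)
    significant = observed > np.quantile(perm_values, 1 - criterion)
    return SignificanceResult(p, observed, perm_values, significant)


# ---------------------------------------------------------------------------
# Toy geometry
# ---------------------------------------------------------------------------

def toy_grid(n_per_axis: int = 5, spacing: float = 20.0) -> np.ndarray:
    """Cubic source grid centered at the origin, coordinates in mm."""
    half = (n_per_axis - 1) / 2
    axis = (np.arange(n_per_axis) - half) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def make_toy_leadfield(
    n_sensors: int = 32,
    source_coords: np.ndarray | None = None,
    head_radius: float = 90.0,
    seed: int = 0,
) -> LeadField:
    """Distance-falloff gain over a spherical sensor montage.

    Sensors are placed quasi-uniformly on the upper hemisphere of a
    sphere of ``head_radius`` mm (Fibonacci lattice); the gain from
    source q to sensor k decays as ``1 / (|r_k - r_q|^2 + r0^2)``.  This
    is a smooth geometric toy forward model — adequate for exercising
    the beamformer algebra, not a physical volume-conductor solution.
    """
    if source_coords is None:
        source_coords = toy_grid()
    source_coords = np.asarray(source_coords, dtype=float)
    i = np.arange(n_sensors)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    z = i / max(n_sensors - 1, 1)  # upper hemisphere
    r_xy = np.sqrt(np.clip(1 - z**2, 0, None))
    sensors = head_radius * np.column_stack(
        [r_xy * np.cos(theta), r_xy * np.sin(theta), z]
    )
    d2 = ((sensors[:, None, :] - source_coords[None, :, :]) ** 2).sum(-1)
    r0 = 25.0
    gain = 1.0 / (d2 + r0**2)
    gain *= 1e4 / np.abs(gain).max()
    return LeadField(gain, sensors, source_coords, head_model="toy-sphere-distance")
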