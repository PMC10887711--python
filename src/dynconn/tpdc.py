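"""Time-resolved directed connectivity via dual-Kalman tPDC.

The estimand is time-resolved Partial Directed Coherence (tPDC): the
column-normalized frequency response of a time-varying multivariate
autoregressive (MVAR) model,

.. math::

    \\bar A(f, t) = I - \\sum_{r=1}^{p} A_r(t)\\, e^{-i 2\\pi f r / f_s},
    \\qquad
    \\pi_{ij}(f, t) = \\frac{|\\bar A_{ij}(f, t)|}
                           {\\sqrt{\\sum_k |\\bar A_{kj}(f, t)|^2}},

where :math:`\\pi_{ij}` measures the directed influence of channel *j*
on channel *i* and every column satisfies
:math:`\\sum_i \\pi_{ij}^2 = 1`.

The time-varying coefficients :math:`A_r(t)` are tracked with a dual
extended Kalman filter (DEKF): a state filter estimates the lagged
signal state given the current parameters, and a parameter filter
tracks :math:`\\mathrm{vec}(A_1 \\dots A_p)` under a random-walk model,
each feeding the other at every sample.  :class:`DEKF` is the model
object; ``fit()`` returns :class:`DEKFResults` with the coefficient
trajectory, diagnostics, and the tPDC tensor.

Edge-level inference combines a window-shuffling surrogate threshold
(temporal order destroyed, instantaneous covariance preserved) with
time-reversal validation (directed asymmetries must invert when the
data are played backwards), guarding against volume-conduction-like
zero-lag mixing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BandDefinition, MultichannelSeries

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return f if args and callable(args[0]) else wrap


logger = logging.getLogger(__name__)

__all__ = [
    "DEKF",
    "DEKFResults",
    "TPDCTensor",
    "ConnectivityGraph",
    "GraphEdge",
    "fit_mvar_ls",
    "pdc_spectrum",
    "tpdc_compute",
    "edge_strengths",
    "bootstrap_threshold",
    "time_reversal_test",
    "build_graph",
    "group_mean_directional_coherence",
    "recover_network",
    "band_freqs",
]


# ---------------------------------------------------------------------------
# Least-squares MVAR (initialization and oracle)
# ---------------------------------------------------------------------------

def fit_mvar_ls(
    data: np.ndarray, order: int, rcond: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of a static MVAR(p).

    ``data`` is (n_channels, n_samples).  Returns coefficients of shape
    ``(p, m, m)`` and the residual (innovation) covariance.  Singular
    values below ``rcond`` times the largest are truncated, so the fit
    stays bounded on near-collinear narrowband data (the minimum-norm
    solution is returned along ill-determined directions).
    """
    m, T = data.shape
    p = order
    if T <= p * m + p:
        raise ValueError("series too short for least-squares MVAR fit")
    Y = data[:, p:].T                               # (T-p, m)
    X = np.concatenate(
        [data[:, p - r - 1 : T - r - 1].T for r in range(p)], axis=1
    )                                               # (T-p, m*p)
    B, *_ = np.linalg.lstsq(X, Y, rcond=rcond)      # (m*p, m)
    resid = Y - X @ B
    sigma = resid.T @ resid / max(resid.shape[0] - m * p, 1)
    coeffs = np.stack(
        [B[r * m : (r + 1) * m].T for r in range(p)], axis=0
    )
    return coeffs, sigma


# ---------------------------------------------------------------------------
# DEKF core loop
# ---------------------------------------------------------------------------

def _dekf_loop(y, p, A0, W, q, r_obs, p0_theta, p0_state, max_norm):
    T, m = y.shape
    mp = m * p
    A = A0.copy()                      # (m, mp) parameter estimate
    Pth = np.eye(m * mp) * p0_theta
    Px = np.eye(mp) * p0_state
    Rth = W + np.eye(m) * r_obs
    Xs = np.zeros(mp)
    for r in range(p):
        Xs[r * m : (r + 1) * m] = y[p - 1 - r]
    traj = np.zeros((T, m, mp))
    pred_err = np.zeros((T, m))
    for t in range(p):
        traj[t] = A
    qI = q
    for t in range(p, T):
        # ---- parameter filter: predict + update with innovation e
        for d in range(m * mp):
            Pth[d, d] += qI
        xpred = A @ Xs
        e = y[t] - xpred
        PHt = np.zeros((m * mp, m))
        for j in range(m):
            PHt[:, j] = Pth[:, j * mp : (j + 1) * mp] @ Xs
        S = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                S[i, j] = Xs @ PHt[i * mp : (i + 1) * mp, j]
        S = S + Rth
        Sinv = np.linalg.inv(S)
        K = PHt @ Sinv                  # (m*mp, m)
        dtheta = K @ e
        for i in range(m):
            A[i] += dtheta[i * mp : (i + 1) * mp]
        Pth = Pth - K @ PHt.T
        Pth = 0.5 * (Pth + Pth.T)
        # ---- state filter with updated parameters
        Xpred = np.zeros(mp)
        Xpred[:m] = A @ Xs
        Xpred[m:] = Xs[: mp - m]
        F = np.zeros((mp, mp))
        F[:m] = A
        for d in range(mp - m):
            F[m + d, d] = 1.0
        Pxp = F @ Px @ F.T
        Pxp[:m, :m] += W
        Sx = Pxp[:m, :m] + np.eye(m) * r_obs
        Kx = Pxp[:, :m] @ np.linalg.inv(Sx)
        Xs = Xpred + Kx @ (y[t] - Xpred[:m])
        Px = Pxp - Kx @ Pxp[:m, :]
        traj[t] = A
        pred_err[t] = e
        if t % 200 == 0:
            nrm = 0.0
            for i in range(m):
                for k in range(mp):
                    nrm += A[i, k] * A[i, k]
            if not np.isfinite(nrm) or nrm > max_norm * max_norm:
                return traj, pred_err, -1
    return traj, pred_err, 0


if _HAVE_NUMBA:
    _dekf_loop_jit = njit(cache=True)(_dekf_loop)
else:  # pragma: no cover
    _dekf_loop_jit = _dekf_loop


class DEKF:
    """Dual extended Kalman filter for time-varying MVAR coefficients.

    Parameters
    ----------
    series : MultichannelSeries
        The multichannel signal to model.
    order : int
        MVAR model order p (default 5 — covers mu/beta dynamics at
        500 Hz).
    q_param : float
        Random-walk process-noise variance of each parameter (default
        1e-5); larger values track faster changes at the cost of noisier
        trajectories and, for near-unit-root oscillators, a shrinkage
        bias on the collinear autoregressive terms.
    r_obs : float, optional
        Observation-noise variance; defaults to 1e-3 times the mean
        innovation variance estimated on the initialization window.
    init : {"ls", "zero"}
        Parameter initialization: least-squares MVAR fit on the first
        ``init_window`` seconds (default) or zeros.
    init_window : float
        Length (s) of the initialization window (default 2 s).
    """

    def __init__(
        self,
        series: MultichannelSeries,
        order: int = 5,
        q_param: float = 1e-5,
        r_obs: float | None = None,
        init: str = "ls",
        init_window: float = 2.0,
        p0_theta: float = 0.1,
        p0_state: float = 0.1,
        max_norm: float = 1e3,
    ) -> None:
        if order < 1:
            raise ValueError("order must be >= 1")
        m, T = series.data.shape
        if T < 10 * order * m:
            raise ValueError(
                f"series of {T} samples too short for order {order} with "
                f"{m} channels (need >= {10 * order * m})"
            )
        if not np.isfinite(series.data).all():
            raise ValueError("series contains non-finite values")
        self.series = series
        self.order = order
        self.q_param = q_param
        self.r_obs = r_obs
        self.init = init
        self.init_window = init_window
        self.p0_theta = p0_theta
        self.p0_state = p0_state
        self.max_norm = max_norm

    def fit(self) -> "DEKFResults":
        y = self.series.data.T.copy()
        T, m = y.shape
        p = self.order
        n0 = min(T, max(int(self.init_window * self.series.rate), p * m + p + 2))
        if self.init == "ls":
            A0_blocks, W = fit_mvar_ls(y[:n0].T, p)
            A0 = np.concatenate(list(A0_blocks), axis=1)
            if np.linalg.norm(A0) > 0.1 * self.max_norm:
                logger.warning(
                    "ill-conditioned least-squares initialization "
                    "(norm %.3g); falling back to zeros", np.linalg.norm(A0),
                )
                A0 = np.zeros((m, m * p))
                W = np.cov(y[:n0].T, ddof=1)
        elif self.init == "zero":
            A0 = np.zeros((m, m * p))
            W = np.cov(y[:n0].T, ddof=1)
        else:
            raise ValueError(f"unknown init {self.init!r}")
        W = 0.5 * (W + W.T) + 1e-10 * np.eye(m)
        r_obs = self.r_obs
        if r_obs is None:
            r_obs = 1e-3 * float(np.mean(np.diag(W)))
        traj, pred_err, status = _dekf_loop_jit(
            y, p, A0, W, self.q_param, r_obs,
            self.p0_theta, self.p0_state, self.max_norm,
        )
        if status != 0:
            raise RuntimeError(
                "DEKF diverged: parameter norm exceeded "
                f"{self.max_norm}; consider smaller q_param or a lower order "
                f"(order={p}, q_param={self.q_param})"
            )
        warmup = min(max(10 * p, 100), T - 1)
        return DEKFResults(self, traj, pred_err, W, r_obs, warmup)


class DEKFResults:
    """Fitted time-varying MVAR: coefficient trajectory and diagnostics."""

    def __init__(
        self,
        model: DEKF,
        traj: np.ndarray,
        pred_err: np.ndarray,
        innovation_cov: np.ndarray,
        r_obs: float,
        warmup: int,
    ) -> None:
        self.model = model
        self._traj = traj              # (T, m, m*p), full length
        self.prediction_error = pred_err
        self.innovation_cov = innovation_cov
        self.r_obs = r_obs
        self.warmup = warmup

    @property
    def order(self) -> int:
        return self.model.order

    @property
    def n_channels(self) -> int:
        return self._traj.shape[1]

    @property
    def coeff_trajectory(self) -> np.ndarray:
        """Post-warm-up coefficients, shape (T_kept, p, m, m)."""
        m, p = self.n_channels, self.order
        kept = self._traj[self.warmup :]
        return kept.reshape(-1, m, p, m).transpose(0, 2, 1, 3)

    @property
    def time_averaged_coeffs(self) -> np.ndarray:
        """Trajectory mean, shape (p, m, m) — the static-model estimate."""
        return self.coeff_trajectory.mean(axis=0)

    def tpdc(
        self,
        freqs: np.ndarray | None = None,
        band: BandDefinition | None = None,
        stride: int = 1,
        n_freqs: int = 9,
        max_elements: float = 5e7,
    ) -> "TPDCTensor":
        """Time-resolved PDC tensor over the kept trajectory.

        Frequencies come either from ``freqs`` directly or as
        ``n_freqs`` points spanning ``band``; ``stride`` decimates the
        time axis.
        """
        rate = self.model.series.rate
        if freqs is None:
            if band is None:
                raise ValueError("pass freqs or band")
            freqs = band_freqs(band, n_freqs)
        coeffs = self.coeff_trajectory[::stride]
        return tpdc_compute(
            coeffs, np.asarray(freqs, float), rate,
            t0=self.model.series.t0 + self.warmup / rate,
            dt=stride / rate, max_elements=max_elements,
        )

    def summary(self) -> pd.DataFrame:
        """Per-coefficient table: trajectory mean and standard deviation."""
        traj = self.coeff_trajectory
        p, m = self.order, self.n_channels
        rows = []
        labels = self.model.series.labels
        for r in range(p):
            for i in range(m):
                for j in range(m):
                    rows.append(
                        {
                            "lag": r + 1,
                            "target": labels[i],
                            "source": labels[j],
                            "mean": traj[:, r, i, j].mean(),
                            "sd": traj[:, r, i, j].std(),
                        }
                    )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PDC spectra
# ---------------------------------------------------------------------------

def band_freqs(band: BandDefinition, n_freqs: int = 9) -> np.ndarray:
    """Evaluation frequencies spanning a band (inclusive endpoints)."""
    return np.linspace(band.f_lo, band.f_hi, n_freqs)


def decimate_series(series: MultichannelSeries, factor: int) -> MultichannelSeries:
    """Zero-phase FIR decimation of every channel.

    MVAR estimation of 8-20 Hz dynamics at a 500 Hz sampling rate is
    badly conditioned (adjacent lags are nearly collinear); decimating
    to ~125 Hz before fitting restores identifiability without touching
    the band of interest.
    """
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return series
    from scipy.signal import decimate as _dec

    data = _dec(series.data, factor, ftype="fir", zero_phase=True, axis=-1)
    return MultichannelSeries(
        np.ascontiguousarray(data), series.rate / factor,
        list(series.labels), series.t0,
    )


def pdc_spectrum(
    coeffs: np.ndarray, freqs: np.ndarray, rate: float
) -> np.ndarray:
    """PDC of one coefficient set, shape (m, m, n_freqs).

    ``out[i, j, f]`` is the normalized directed influence of channel j
    on channel i at frequency ``freqs[f]``; every column j satisfies
    ``sum_i out[i, j, f]**2 == 1``.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
        raise ValueError("coeffs must have shape (p, m, m)")
    if not np.isfinite(coeffs).all():
        raise ValueError("coefficients must be finite")
    out = tpdc_compute(coeffs[np.newaxis], np.asarray(freqs, float), rate)
    return out.values[:, :, :, 0]


def tpdc_compute(
    coeff_trajectory: np.ndarray,
    freqs: np.ndarray,
    rate: float,
    t0: float = 0.0,
    dt: float | None = None,
    max_elements: float = 5e7,
) -> "TPDCTensor":
    """Apply the PDC transform at every retained time step.

    ``coeff_trajectory`` has shape (T, p, m, m); the result holds
    ``pi_ij(f, t)`` as an (m, m, F, T) tensor.
    """
    A = np.asarray(coeff_trajectory, dtype=float)
    if A.ndim != 4:
        raise ValueError("coeff_trajectory must have shape (T, p, m, m)")
    T, p, m, _ = A.shape
    freqs = np.asarray(freqs, dtype=float)
    F = len(freqs)
    if m * m * F * T > max_elements:
        raise MemoryError(
            f"tPDC tensor would hold {m * m * F * T:.3g} elements "
            f"(cap {max_elements:.3g}); decimate time with a larger stride"
        )
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(lags, freqs) / rate)  # (p, F)
    Abar = np.eye(m)[np.newaxis, np.newaxis] - np.einsum(
        "tpij,pf->tfij", A, phase
    )                                                            # (T, F, m, m)
    mag = np.abs(Abar)
    denom = np.sqrt((mag**2).sum(axis=2, keepdims=True))         # over rows i
    values = (mag / denom).transpose(2, 3, 1, 0)                 # (m, m, F, T)
    dt = 1.0 / rate if dt is None else dt
    times = t0 + dt * np.arange(T)
    return TPDCTensor(values, freqs, times)


@dataclass
class TPDCTensor:
    """Directed coherence values ``pi_ij(f, t)`` as an (m, m, F, T) array."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be (m, m, F, T)")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("tPDC entries must lie in [0, 1]")
        self.values = v
        if not self.labels:
            self.labels = [f"s{i}" for i in range(v.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def column_norm_deviation(self) -> float:
        """Max deviation of ``sum_i pi_ij^2`` from 1 over all (j, f, t)."""
        colsum = (self.values**2).sum(axis=0)
        return float(np.abs(colsum - 1.0).max())

    def band_time_mean(self, band: BandDefinition | None = None) -> np.ndarray:
        """Mean over (band) frequency bins and time: the (m, m) strengths.

        Entry ``[i, j]`` summarizes the influence j -> i.
        """
        if band is None:
            sel = np.ones(len(self.freqs), dtype=bool)
        else:
            sel = (self.freqs >= band.f_lo) & (self.freqs <= band.f_hi)
            if not sel.any():
                raise ValueError("no tensor frequencies inside band")
        return self.values[:, :, sel, :].mean(axis=(2, 3))


# ---------------------------------------------------------------------------
# Edge strengths, surrogates, time reversal
# ---------------------------------------------------------------------------

def edge_strengths(
    series: MultichannelSeries,
    order: int,
    band: BandDefinition,
    estimator: str = "dekf",
    stride: int = 10,
    n_freqs: int = 9,
    standardize: bool = True,
    decimate: int = 1,
    **dekf_kwargs,
) -> np.ndarray:
    """Band-and-time-mean tPDC matrix; ``[i, j]`` is the strength j -> i.

    ``estimator="dekf"`` runs the dual-Kalman tracker (default);
    ``"ls"`` uses a static least-squares MVAR fit, which on stationary
    data estimates the same quantity at a fraction of the cost.
    Channels are standardized to unit variance first (default), since
    plain PDC is not scale-invariant and heterogeneous source variances
    would otherwise distort the column normalization.
    """
    series = decimate_series(series, decimate)
    if standardize:
        sd = series.data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        series = MultichannelSeries(
            series.data / sd, series.rate, list(series.labels), series.t0
        )
    freqs = band_freqs(band, n_freqs)
    if estimator == "dekf":
        res = DEKF(series, order=order, **dekf_kwargs).fit()
        return res.tpdc(freqs=freqs, stride=stride).band_time_mean()
    if estimator == "ls":
        coeffs, _ = fit_mvar_ls(series.data, order)
        pdc = pdc_spectrum(coeffs, freqs, series.rate)
        return pdc.mean(axis=2)
    raise ValueError(f"unknown estimator {estimator!r}")


def bootstrap_threshold(
    series: MultichannelSeries,
    order: int,
    band: BandDefinition,
    n_boot: int = 100,
    window_len: float = 1.0,
    seed: int = 0,
    mode: str = "percentile",
    percentile: float = 95.0,
    scope: str = "per_edge",
    estimator: str = "dekf",
    stride: int = 10,
    n_freqs: int = 9,
    shuffle: str = "per_channel",
    decimate: int = 1,
    **dekf_kwargs,
) -> np.ndarray:
    """Surrogate significance threshold for every directed edge.

    The series is cut into non-overlapping ``window_len``-second windows
    whose order is shuffled — independently per channel by default, which
    destroys cross-channel coupling while preserving each channel's own
    dynamics, giving a proper null for directed interactions
    (``shuffle="joint"`` permutes all channels with one ordering instead,
    but then within-window lagged coupling survives and the surrogate
    distribution collapses onto the observed values).  The MVAR model is
    refitted to each of the ``n_boot`` surrogates, and the band-time-mean
    tPDC is recorded.  ``mode="percentile"`` (default) thresholds each
    edge at the ``percentile``-th surrogate percentile; ``mode="mean"``
    uses the surrogate mean, the literal averaged-surrogate rule — note
    that a mean threshold flags roughly half of all null edges, so the
    percentile mode is the default.  ``scope="global"`` pools
    off-diagonal surrogate values into one scalar threshold for all
    connections.

    Returns an (m, m) threshold matrix (diagonal set to +inf).
    """
    if mode == "mean":
        logger.warning(
            "bootstrap_threshold(mode='mean'): thresholding at the surrogate "
            "mean flags ~half of null edges; 'percentile' is recommended"
        )
    series = decimate_series(series, decimate)
    win = int(round(window_len * series.rate))
    n_win = series.n_samples // win
    if n_win < 2:
        raise ValueError(
            f"window_len={window_len} s leaves fewer than 2 shuffling windows"
        )
    rng = np.random.default_rng(seed)
    m = series.n_channels
    blocks = series.data[:, : n_win * win].reshape(m, n_win, win)
    if shuffle not in ("per_channel", "joint"):
        raise ValueError(f"unknown shuffle {shuffle!r}")
    boots = np.empty((n_boot, m, m))
    for b in range(n_boot):
        if shuffle == "joint":
            shuf = blocks[:, rng.permutation(n_win), :]
        else:
            shuf = np.stack(
                [blocks[c, rng.permutation(n_win), :] for c in range(m)]
            )
        surr = MultichannelSeries(
            shuf.reshape(m, n_win * win),
            series.rate, list(series.labels),
        )
        boots[b] = edge_strengths(
            surr, order, band, estimator=estimator, stride=stride,
            n_freqs=n_freqs, **dekf_kwargs,
        )
    if scope == "global":
        off = ~np.eye(m, dtype=bool)
        pooled = boots[:, off].ravel()
        # "higher" keeps the exceedance probability at or below the
        # nominal level for finite surrogate counts
        thr_val = (
            float(np.mean(pooled)) if mode == "mean"
            else float(np.percentile(pooled, percentile, method="higher"))
        )
        thr = np.full((m, m), thr_val)
    elif scope == "per_edge":
        thr = (
            boots.mean(axis=0) if mode == "mean"
            else np.percentile(boots, percentile, axis=0, method="higher")
        )
    else:
        raise ValueError(f"unknown scope {scope!r}")
    np.fill_diagonal(thr, np.inf)
    return thr


def time_reversal_test(
    series: MultichannelSeries,
    candidate_edges: list[tuple[int, int]],
    order: int,
    band: BandDefinition,
    gamma: float = 0.5,
    estimator: str = "dekf",
    strengths: np.ndarray | None = None,
    stride: int = 10,
    n_freqs: int = 9,
    mode: str = "reduction",
    decimate: int = 1,
    **dekf_kwargs,
) -> dict[tuple[int, int], bool]:
    """Time-reversal validation of candidate directed edges.

    For each candidate ``(src, dst)``, the directed asymmetry
    ``delta = strength(src->dst) - strength(dst->src)`` is computed on
    the original and the time-reversed series.  A genuinely lagged
    (causal) interaction must revert when the data are played backwards,
    while zero-lag (volume-conduction-like) mixing produces weak
    asymmetries that reversal leaves unchanged.

    ``mode="reduction"`` (default): the edge passes iff its direction
    dominates on the original data (``delta > 0``) and reversal removes
    at least the fraction ``gamma`` of the asymmetry
    (``delta_reversed <= (1 - gamma) * delta``); a full sign flip always
    passes.  ``mode="strict"`` additionally demands a sign flip with
    ``|delta_reversed| >= gamma * |delta|`` — in multichannel narrowband
    systems the reversed asymmetry collapses toward zero rather than
    mirroring, so the strict rule rejects most genuine interactions and
    is kept only for comparison.
    """
    if not candidate_edges:
        return {}
    series = decimate_series(series, decimate)
    if strengths is None:
        strengths = edge_strengths(
            series, order, band, estimator=estimator, stride=stride,
            n_freqs=n_freqs, **dekf_kwargs,
        )
    reversed_series = MultichannelSeries(
        series.data[:, ::-1].copy(), series.rate, list(series.labels)
    )
    strengths_rev = edge_strengths(
        reversed_series, order, band, estimator=estimator, stride=stride,
        n_freqs=n_freqs, **dekf_kwargs,
    )
    out: dict[tuple[int, int], bool] = {}
    for src, dst in candidate_edges:
        d_orig = strengths[dst, src] - strengths[src, dst]
        d_rev = strengths_rev[dst, src] - strengths_rev[src, dst]
        if mode == "strict":
            flips = np.sign(d_rev) == -np.sign(d_orig) and d_orig != 0
            out[(src, dst)] = bool(flips and abs(d_rev) >= gamma * abs(d_orig))
        elif mode == "reduction":
            out[(src, dst)] = bool(
                d_orig > 0 and d_rev <= (1 - gamma) * d_orig
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# Connectivity graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GraphEdge:
    """One directed connection with its inference annotations."""

    src: int
    dst: int
    band: str
    strength: float
    threshold: float
    significant: bool
    trt_pass: bool | None
    length_mm: float | None


@dataclass
class ConnectivityGraph:
    """Directed graph over localized sources with significance flags."""

    node_labels: list[str]
    coords: np.ndarray | None
    band: BandDefinition
    edges: list[GraphEdge]

    def significant_edges(self) -> list[GraphEdge]:
        return [e for e in self.edges if e.significant]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "src": self.node_labels[e.src],
                    "dst": self.node_labels[e.dst],
                    "band": e.band,
                    "strength": e.strength,
                    "threshold": e.threshold,
                    "significant": e.significant,
                    "trt_pass": e.trt_pass,
                    "length_mm": e.length_mm,
                }
                for e in self.edges
            ]
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for i, lab in enumerate(self.node_labels):
            coord = None if self.coords is None else tuple(self.coords[i])
            g.add_node(lab, coord=coord)
        for e in self.significant_edges():
            g.add_edge(
                self.node_labels[e.src], self.node_labels[e.dst],
                strength=e.strength, length_mm=e.length_mm,
            )
        return g


def build_graph(
    node_labels: list[str],
    strengths: np.ndarray,
    thresholds: np.ndarray,
    band: BandDefinition,
    trt_flags: dict[tuple[int, int], bool] | None = None,
    coords: np.ndarray | None = None,
) -> ConnectivityGraph:
    """Assemble the annotated connectivity graph.

    ``strengths[i, j]`` is the influence j -> i; an edge ``src -> dst``
    is significant iff its strength exceeds its threshold AND (when
    time-reversal flags are supplied) it passed the time-reversal test.
    Edge lengths are Euclidean distances between node coordinates (mm);
    omitted with a warning when coordinates are missing.
    """
    strengths = np.asarray(strengths, dtype=float)
    m = len(node_labels)
    if strengths.shape != (m, m):
        raise ValueError("strengths must be (m, m)")
    thresholds = np.broadcast_to(np.asarray(thresholds, dtype=float), (m, m))
    if coords is None:
        warnings.warn("node coordinates missing; edge lengths omitted")
    edges = []
    for src in range(m):
        for dst in range(m):
            if src == dst:
                continue
            s = float(strengths[dst, src])
            thr = float(thresholds[dst, src])
            above = s > thr
            trt = None if trt_flags is None else trt_flags.get((src, dst), False)
            sig = above and (trt is None or trt)
            length = (
                None if coords is None
                else float(np.linalg.norm(coords[src] - coords[dst]))
            )
            edges.append(
                GraphEdge(src, dst, band.name, s, thr, sig, trt, length)
            )
    return ConnectivityGraph(list(node_labels), coords, band, edges)


def group_mean_directional_coherence(
    graph: ConnectivityGraph,
) -> tuple[float, bool]:
    """Subject-level mean tPDC over significant edges.

    Returns ``(mean_strength, has_significant)``; the mean is 0.0 with
    the flag False when no edge is significant.
    """
    sig = graph.significant_edges()
    if not sig:
        return 0.0, False
    return float(np.mean([e.strength for e in sig])), True


# ---------------------------------------------------------------------------
# One-subject recovery pipeline
# ---------------------------------------------------------------------------

def recover_network(
    series: MultichannelSeries,
    order: int,
    band: BandDefinition,
    coords: np.ndarray | None = None,
    node_labels: list[str] | None = None,
    n_boot: int = 100,
    window_len: float = 1.0,
    seed: int = 0,
    threshold_mode: str = "percentile",
    scope: str = "per_edge",
    gamma: float = 0.5,
    use_trt: bool = True,
    estimator: str = "dekf",
    stride: int = 10,
    n_freqs: int = 9,
    decimate: int = 1,
    **dekf_kwargs,
) -> ConnectivityGraph:
    """Full edge inference for one subject's source signals.

    Estimates band-time-mean tPDC strengths, a window-shuffling
    surrogate threshold, applies the time-reversal test to
    supra-threshold candidates, and returns the annotated graph.
    ``decimate`` downsamples once at entry (recommended: to ~125 Hz for
    mu/beta dynamics recorded at 500 Hz) before any estimation.
    """
    series = decimate_series(series, decimate)
    labels = node_labels or list(series.labels)
    strengths = edge_strengths(
        series, order, band, estimator=estimator, stride=stride,
        n_freqs=n_freqs, **dekf_kwargs,
    )
    thr = bootstrap_threshold(
        series, order, band, n_boot=n_boot, window_len=window_len, seed=seed,
        mode=threshold_mode, scope=scope, estimator=estimator, stride=stride,
        n_freqs=n_freqs, **dekf_kwargs,
    )
    m = series.n_channels
    candidates = [
        (j, i) for i in range(m) for j in range(m)
        if i != j and strengths[i, j] > thr[i, j]
    ]
    trt_flags = None
    if use_trt:
        trt_flags = time_reversal_test(
            series, candidates, order, band, gamma=gamma, estimator=estimator,
            strengths=strengths, stride=stride, n_freqs=n_freqs, **dekf_kwargs,
        )
    return build_graph(labels, strengths, thr, band, trt_flags, coords)
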