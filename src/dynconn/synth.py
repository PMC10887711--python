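"""Synthetic inputs for every pipeline stage.

Real recordings of the kind this pipeline targets (64-channel, 500 Hz EEG
during point-light-walker viewing) are not publicly deposited, so this
module generates everything downstream stages need with known ground
truth:

* directed oscillatory source networks as stable (time-varying) MVAR
  models, with a "dense long-range" profile mimicking a typically
  developing control group and a "sparse local" profile mimicking a
  reduced long-range connectivity group;
* sensor projections through a lead field with additive white noise;
* signal-detection behavior (hits / false alarms) at a controllable d';
* point-light walker dot trajectories and their "scramble" control, in
  which each dot keeps its path shape and cycle frequency but moves at
  constant speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .core import BandDefinition, MultichannelSeries

__all__ = [
    "MVARSpec",
    "Edge",
    "GroupNetworkProfile",
    "DENSE_LONGRANGE",
    "SPARSE_LOCAL",
    "SignalDetectionCounts",
    "BehavioralSession",
    "DotTrajectories",
    "template_coords",
    "make_group_network",
    "simulate_mvar",
    "project_to_sensors",
    "simulate_behavior",
    "make_walker",
    "scramble_transform",
]


# ---------------------------------------------------------------------------
# MVAR specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edge:
    """A directed ground-truth connection ``src -> dst`` at a given lag."""

    src: int
    dst: int
    lag: int
    coeff: float


@dataclass
class MVARSpec:
    """A (possibly time-varying) multivariate autoregressive model.

    ``coeffs`` has shape ``(p, m, m)`` for a static model or
    ``(T, p, m, m)`` for a coefficient trajectory.  ``coeffs[r, i, j]``
    is the influence of channel ``j`` at lag ``r + 1`` on channel ``i``.
    """

    coeffs: np.ndarray
    innovation_cov: np.ndarray
    labels: list[str] = field(default_factory=list)
    coords: np.ndarray | None = None
    edges: list[Edge] | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim not in (3, 4):
            raise ValueError("coeffs must have shape (p, m, m) or (T, p, m, m)")
        m = self.coeffs.shape[-1]
        if self.coeffs.shape[-2] != m:
            raise ValueError("coefficient blocks must be square")
        self.innovation_cov = np.asarray(self.innovation_cov, dtype=float)
        if self.innovation_cov.shape != (m, m):
            raise ValueError(
                f"innovation_cov must be {m}x{m}, got {self.innovation_cov.shape}"
            )
        if not np.allclose(self.innovation_cov, self.innovation_cov.T, atol=1e-10):
            raise ValueError("innovation_cov must be symmetric")
        eigvals = np.linalg.eigvalsh(self.innovation_cov)
        if eigvals.min() < -1e-10:
            raise ValueError(
                f"innovation_cov must be positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        if not self.labels:
            self.labels = [f"s{i}" for i in range(m)]
        if len(self.labels) != m:
            raise ValueError("label count must equal number of nodes")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (m, 3):
                raise ValueError("coords must be (m, 3) mm triples")

    @property
    def n_nodes(self) -> int:
        return self.coeffs.shape[-1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[-3]

    @property
    def is_time_varying(self) -> bool:
        return self.coeffs.ndim == 4

    def companion(self, t: int | None = None) -> np.ndarray:
        """Companion matrix of the coefficients (at step ``t`` if time-varying)."""
        A = self.coeffs[t] if self.is_time_varying else self.coeffs
        return companion_matrix(A)

    def spectral_radius(self) -> float:
        """Largest companion-eigenvalue modulus (static spec only)."""
        if self.is_time_varying:
            raise ValueError("spectral radius is defined for static specs")
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Stack ``(p, m, m)`` AR blocks into the ``mp x mp`` companion form."""
    p, m, _ = coeffs.shape
    comp = np.zeros((m * p, m * p))
    comp[:m] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[m:, : m * (p - 1)] = np.eye(m * (p - 1))
    return comp


# ---------------------------------------------------------------------------
# Group network profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupNetworkProfile:
    """Structural recipe for a group-dependent directed source network.

    ``dense_longrange`` emulates a control-like group: many directed
    edges including long anterior-posterior connections.  ``sparse_local``
    emulates a group with few, short-range connections; all its edges
    must be shorter than ``max_edge_length``.
    """

    name: str
    n_nodes: int
    n_edges: int
    min_edge_length: float = 80.0  # dense profile: at least one edge >= this (mm)
    max_edge_length: float = 85.0  # sparse profile: all edges <= this (mm)
    edge_strength_range: tuple[float, float] = (0.25, 0.4)

    def __post_init__(self) -> None:
        if self.name not in ("dense_longrange", "sparse_local"):
            raise ValueError(f"unknown profile name {self.name!r}")
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not 0 <= self.n_edges <= self.n_nodes * (self.n_nodes - 1):
            raise ValueError(
                f"n_edges={self.n_edges} exceeds n_nodes*(n_nodes-1)="
                f"{self.n_nodes * (self.n_nodes - 1)}"
            )


#: Control-like profile: 10 directed mu-band edges over 5 sources, with
#: stronger per-connection coupling (group differences in directed
#: interaction strength, not only edge count, are part of the emulated
#: phenomenon).
DENSE_LONGRANGE = GroupNetworkProfile(
    "dense_longrange", n_nodes=5, n_edges=10,
    edge_strength_range=(0.3, 0.45),
)
#: Reduced-connectivity profile: 4 short, weaker edges over 5 sources.
SPARSE_LOCAL = GroupNetworkProfile(
    "sparse_local", n_nodes=5, n_edges=4,
    edge_strength_range=(0.18, 0.3),
)


def template_coords(n_nodes: int) -> np.ndarray:
    """Fixed pseudo-MNI node positions (mm) on an occipital-to-frontal axis.

    Five canonical positions span visual cortex to prefrontal cortex;
    other node counts interpolate along the same posterior-anterior axis
    with alternating lateralization, so that "long-range" edges
    (> ~80 mm) exist whenever nodes sample both ends of the axis.
    """
    canonical = np.array(
        [
            [0.0, -92.0, 2.0],   # occipital / visual
            [-44.0, -68.0, 8.0],  # inferior temporal
            [46.0, -52.0, 44.0],  # parietal
            [-48.0, 12.0, 28.0],  # inferior frontal
            [6.0, 46.0, 30.0],    # medial prefrontal
        ]
    )
    if n_nodes == 5:
        return canonical.copy()
    y = np.linspace(-92.0, 46.0, n_nodes)
    x = np.array([(-1) ** i * (40.0 if 0 < i < n_nodes - 1 else 0.0)
                  for i in range(n_nodes)])
    z = np.linspace(2.0, 30.0, n_nodes)
    return np.column_stack([x, y, z])


def _candidate_pairs(coords: np.ndarray, profile: GroupNetworkProfile) -> list[tuple[int, int, float]]:
    m = coords.shape[0]
    pairs = []
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if profile.name == "sparse_local" and d > profile.max_edge_length:
                continue
            pairs.append((i, j, d))
    return pairs


def make_group_network(
    profile: GroupNetworkProfile,
    band: BandDefinition,
    seed: int,
    rate: float = 500.0,
    order: int | None = None,
    pole_radius: float = 0.95,
    coupling_lag: int = 5,
    coords: np.ndarray | None = None,
) -> MVARSpec:
    """Build a stable oscillatory MVAR with a known directed edge set.

    Each node is a damped AR(2) oscillator whose resonance lies inside
    ``band`` at the given sampling rate (node frequencies are spread
    evenly across the band).  Directed edges are cross-coefficients at
    ``coupling_lag`` (default 5 samples = 10 ms at 500 Hz, a realistic
    cortico-cortical conduction delay; near-instantaneous lags make the
    direction of narrowband coupling almost invisible to time-reversal
    validation) with magnitudes
    drawn from ``profile.edge_strength_range``; the realized edge list is
    retained on the returned spec.  While the requested edge count allows
    one direction per unordered pair, edges are oriented along a random
    topological order of the nodes: the coupling is then acyclic, the
    companion matrix block-triangular, and stability is inherited from
    the uncoupled oscillators whatever the coupling strengths; it also
    avoids reciprocal pairs, so directed asymmetries survive
    time-reversal validation.  Requests beyond one edge per pair
    introduce feedback loops, and cross-coefficients are then shrunk
    until the spectral radius falls below 0.98.

    Raises
    ------
    ValueError
        If the requested edge count is infeasible under the profile's
        length constraints.
    """
    band.check_nyquist(rate)
    if coupling_lag < 1:
        raise ValueError("coupling_lag must be >= 1")
    if order is None:
        order = max(2, coupling_lag)
    if order < max(2, coupling_lag):
        raise ValueError(
            "order must be >= 2 (oscillatory poles) and >= coupling_lag"
        )
    rng = np.random.default_rng(seed)
    m = profile.n_nodes
    coords = template_coords(m) if coords is None else np.asarray(coords, float)

    pairs = _candidate_pairs(coords, profile)
    if len(pairs) < profile.n_edges:
        raise ValueError(
            f"profile {profile.name!r}: only {len(pairs)} directed pairs satisfy "
            f"the length cap max_edge_length={profile.max_edge_length} mm but "
            f"n_edges={profile.n_edges} were requested"
        )
    if profile.name == "dense_longrange" and profile.n_edges > 0:
        if not any(d >= profile.min_edge_length for _, _, d in pairs):
            raise ValueError(
                f"profile {profile.name!r}: no candidate edge reaches "
                f"min_edge_length={profile.min_edge_length} mm"
            )

    # orient pairs along a random topological order so the coupling is
    # acyclic (block-triangular companion => stability inherited from the
    # uncoupled oscillators); reciprocal directions only when requested
    topo = list(rng.permutation(m))
    rank = {node: k for k, node in enumerate(topo)}

    def _oriented(i: int, j: int, d: float) -> tuple[int, int, float]:
        return (i, j, d) if rank[i] < rank[j] else (j, i, d)

    upairs: dict[frozenset, float] = {}
    for i, j, d in pairs:
        upairs[frozenset((i, j))] = d
    chosen: list[tuple[int, int, float]] = []
    if profile.name == "dense_longrange" and profile.n_edges > 0:
        long_pairs = [
            (tuple(sorted(k))[0], tuple(sorted(k))[1], d)
            for k, d in upairs.items() if d >= profile.min_edge_length
        ]
        i, j, d = long_pairs[int(rng.integers(len(long_pairs)))]
        chosen.append(_oriented(i, j, d))
    # pass 1: one direction per unordered pair, DAG-oriented
    for key in sorted(upairs, key=lambda _: rng.random()):
        if len(chosen) == profile.n_edges:
            break
        if any(frozenset((c[0], c[1])) == key for c in chosen):
            continue
        i, j = sorted(key)
        chosen.append(_oriented(i, j, upairs[key]))
    # pass 2: reciprocal directions if the count demands them (cyclic)
    if len(chosen) < profile.n_edges:
        have = {(c[0], c[1]) for c in chosen}
        for src, dst, d in sorted(pairs, key=lambda _: rng.random()):
            if len(chosen) == profile.n_edges:
                break
            if (src, dst) not in have:
                chosen.append((src, dst, d))
                have.add((src, dst))

    coeffs = np.zeros((order, m, m))
    freqs = np.linspace(band.f_lo, band.f_hi, m + 2)[1:-1]
    innov_var = np.empty(m)
    for i in range(m):
        w = 2 * math.pi * freqs[i] / rate
        a1 = 2 * pole_radius * math.cos(w)
        a2 = -pole_radius**2
        coeffs[0, i, i] = a1
        coeffs[1, i, i] = a2
        # innovation variance making the isolated oscillator unit-variance
        # (stationary variance of an AR(2) with unit innovations)
        gain = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1**2))
        innov_var[i] = 1.0 / gain
    # edge strengths are relative amplitude contributions: the raw
    # cross-coefficient is divided by the target oscillator's gain at the
    # source frequency, so an edge of strength r feeds roughly a fraction
    # r of the target's amplitude regardless of how resonant the target is
    # (otherwise near-unit-root targets amplify any input ~20-fold and
    # variance piles up explosively along directed paths)
    lo, hi = profile.edge_strength_range
    edges = []
    for src, dst, _d in chosen:
        r_strength = float(rng.uniform(lo, hi))
        w_src = 2 * math.pi * freqs[src] / rate
        h = 1.0 - coeffs[0, dst, dst] * np.exp(-1j * w_src) \
            - coeffs[1, dst, dst] * np.exp(-2j * w_src)
        c = r_strength * abs(h)
        coeffs[coupling_lag - 1, dst, src] = c
        edges.append(Edge(src=src, dst=dst, lag=coupling_lag, coeff=c))

    spec = MVARSpec(
        coeffs,
        np.diag(innov_var),
        labels=[f"s{i}" for i in range(m)],
        coords=coords,
        edges=edges,
    )
    # acyclic coupling leaves the radius at pole_radius; feedback loops
    # (reciprocal requests) may push poles outward -> shrink cross-terms
    for _ in range(100):
        if spec.spectral_radius() < 0.98:
            break
        for e in spec.edges:
            spec.coeffs[e.lag - 1, e.dst, e.src] *= 0.9
        spec.edges = [
            Edge(e.src, e.dst, e.lag, spec.coeffs[e.lag - 1, e.dst, e.src])
            for e in spec.edges
        ]
    else:
        raise ValueError("could not stabilize network spec")
    return spec


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_mvar(
    spec: MVARSpec,
    n_samples: int,
    seed: int,
    rate: float = 500.0,
    burn_in: int | None = None,
) -> MultichannelSeries:
    """Drive an MVAR spec with Gaussian innovations.

    Static specs are run for ``burn_in`` extra samples (default ``10 p``)
    which are discarded, so the returned series is approximately
    stationary.  Time-varying specs require ``coeffs`` of length
    ``n_samples`` and use no burn-in.
    """
    p, m = spec.order, spec.n_nodes
    if n_samples <= p:
        raise ValueError(f"n_samples must exceed the model order {p}")
    if not spec.is_time_varying and not spec.is_stable():
        raise ValueError(
            f"unstable MVAR spec: spectral radius "
            f"{spec.spectral_radius():.4f} >= 1; simulation would diverge"
        )
    if spec.is_time_varying and spec.coeffs.shape[0] != n_samples:
        raise ValueError(
            f"time-varying coeffs length {spec.coeffs.shape[0]} != n_samples "
            f"{n_samples}"
        )
    if burn_in is None:
        burn_in = 0 if spec.is_time_varying else 10 * p
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    chol = np.linalg.cholesky(
        spec.innovation_cov + 1e-12 * np.eye(m)
    )
    innov = rng.standard_normal((total, m)) @ chol.T
    x = np.zeros((total, m))
    x[:p] = innov[:p]
    static = not spec.is_time_varying
    A = spec.coeffs if static else None
    for t in range(p, total):
        At = A if static else spec.coeffs[max(t - burn_in, 0)]
        acc = innov[t].copy()
        for r in range(p):
            acc += At[r] @ x[t - r - 1]
        x[t] = acc
    return MultichannelSeries(x[burn_in:].T, rate, list(spec.labels))


def project_to_sensors(
    sources: MultichannelSeries,
    leadfield,
    sensor_noise_sd: float,
    seed: int,
) -> MultichannelSeries:
    """Forward-project source signals to sensors: ``y = G x + noise``.

    ``leadfield`` is a :class:`dynconn.dics.LeadField`; its source count
    must match the number of source channels.
    """
    gain = np.asarray(leadfield.gain, dtype=float)
    if gain.shape[1] != sources.n_channels:
        raise ValueError(
            f"lead field has {gain.shape[1]} sources but series has "
            f"{sources.n_channels} channels"
        )
    rng = np.random.default_rng(seed)
    y = gain @ sources.data
    if sensor_noise_sd > 0:
        y = y + sensor_noise_sd * rng.standard_normal(y.shape)
    return MultichannelSeries(
        y, sources.rate, [f"e{i}" for i in range(gain.shape[0])], t0=sources.t0
    )


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalDetectionCounts:
    """Trial counts for one condition of a yes/no detection task."""

    n_signal_trials: int
    n_noise_trials: int
    hits: int
    false_alarms: int

    def __post_init__(self) -> None:
        if not 0 <= self.hits <= self.n_signal_trials:
            raise ValueError("hits must lie in [0, n_signal_trials]")
        if not 0 <= self.false_alarms <= self.n_noise_trials:
            raise ValueError("false_alarms must lie in [0, n_noise_trials]")

    @property
    def hit_rate(self) -> float:
        return self.hits / self.n_signal_trials

    @property
    def false_alarm_rate(self) -> float:
        return self.false_alarms / self.n_noise_trials


@dataclass
class BehavioralSession:
    """Per-condition signal-detection counts for one subject."""

    conditions: dict[str, SignalDetectionCounts]

    def __getitem__(self, key: str) -> SignalDetectionCounts:
        return self.conditions[key]


def simulate_behavior(
    n_trials: int,
    dprime_true: float,
    criterion: float = 0.0,
    seed: int = 0,
    conditions: Sequence[str] = ("walker", "scramble"),
    dprime_by_condition: Mapping[str, float] | None = None,
) -> BehavioralSession:
    """Draw hits and false alarms under the equal-variance Gaussian model.

    With sensitivity d' and criterion c, the hit probability is
    ``Phi(d'/2 - c)`` and the false-alarm probability ``Phi(-d'/2 - c)``;
    each condition gets ``n_trials`` signal and ``n_trials`` noise trials.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    out: dict[str, SignalDetectionCounts] = {}
    for cond in conditions:
        d = (dprime_by_condition or {}).get(cond, dprime_true)
        p_hit = norm.cdf(d / 2 - criterion)
        p_fa = norm.cdf(-d / 2 - criterion)
        out[cond] = SignalDetectionCounts(
            n_signal_trials=n_trials,
            n_noise_trials=n_trials,
            hits=int(rng.binomial(n_trials, p_hit)),
            false_alarms=int(rng.binomial(n_trials, p_fa)),
        )
    return BehavioralSession(out)


# ---------------------------------------------------------------------------
# Point-light walker stimuli
# ---------------------------------------------------------------------------

@dataclass
class DotTrajectories:
    """2-D dot trajectories over one or more gait cycles.

    ``positions`` has shape ``(n_dots, n_samples, 2)`` in arbitrary
    display units; ``cycle_length`` is the gait-cycle period in samples.
    """

    positions: np.ndarray
    cycle_length: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_dots, n_samples, 2)")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if self.cycle_length < 2:
            raise ValueError("cycle_length must be >= 2 samples")

    @property
    def n_dots(self) -> int:
        return self.positions.shape[0]

    @property
    def n_samples(self) -> int:
        return self.positions.shape[1]


# joint layout: (base_x, base_y, swing_x, swing_y, phase relative to gait cycle)
_JOINTS = [
    ("head", 0.0, 1.75, 0.01, 0.02, 0.0),
    ("neck", 0.0, 1.55, 0.01, 0.02, 0.0),
    ("r_shoulder", 0.18, 1.50, 0.06, 0.02, 0.5),
    ("l_shoulder", -0.18, 1.50, 0.06, 0.02, 0.0),
    ("r_elbow", 0.22, 1.25, 0.12, 0.04, 0.5),
    ("l_elbow", -0.22, 1.25, 0.12, 0.04, 0.0),
    ("r_wrist", 0.24, 1.00, 0.20, 0.06, 0.5),
    ("l_wrist", -0.24, 1.00, 0.20, 0.06, 0.0),
    ("pelvis", 0.0, 1.00, 0.02, 0.03, 0.0),
    ("r_hip", 0.12, 0.95, 0.05, 0.03, 0.0),
    ("l_hip", -0.12, 0.95, 0.05, 0.03, 0.5),
    ("r_knee", 0.13, 0.55, 0.18, 0.06, 0.0),
    ("l_knee", -0.13, 0.55, 0.18, 0.06, 0.5),
    ("r_ankle", 0.14, 0.10, 0.28, 0.10, 0.0),
    ("l_ankle", -0.14, 0.10, 0.28, 0.10, 0.5),
]


def make_walker(
    n_cycles: int = 2,
    rate: float = 60.0,
    step_rate: float = 2.0,
) -> DotTrajectories:
    """Parametric 15-dot point-light walker (frontal view, treadmill).

    A sinusoidal limb-kinematics stand-in for motion-capture data: limbs
    swing at the gait-cycle frequency (``step_rate / 2``, i.e. two steps
    per second gives a 1 Hz cycle), left and right limbs in anti-phase,
    with a small vertical body bounce at the step frequency.
    """
    if n_cycles < 1:
        raise ValueError("need at least one gait cycle")
    cycle_freq = step_rate / 2.0
    cycle_length = int(round(rate / cycle_freq))
    n = cycle_length * n_cycles
    t = np.arange(n) / rate
    phase = 2 * math.pi * cycle_freq * t
    bounce = 0.02 * np.cos(2 * phase)  # body rises twice per cycle
    pos = np.empty((len(_JOINTS), n, 2))
    for k, (_name, bx, by, sx, sy, ph) in enumerate(_JOINTS):
        th = phase + 2 * math.pi * ph
        pos[k, :, 0] = bx + sx * np.sin(th)
        pos[k, :, 1] = by + sy * np.cos(2 * th) + bounce
    return DotTrajectories(pos, cycle_length)


def _constant_speed_retime(path: np.ndarray) -> np.ndarray:
    """Re-parameterize one (T, 2) path to constant speed, same length."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("zero-length trajectory cannot be re-timed")
    target = np.linspace(0.0, total, path.shape[0])
    # strictly increasing abscissa for interpolation
    s_mono = s + np.arange(len(s)) * (1e-12 * max(total, 1.0))
    out = np.column_stack(
        [np.interp(target, s_mono, path[:, 0]), np.interp(target, s_mono, path[:, 1])]
    )
    return out


def scramble_transform(walker: DotTrajectories, seed: int) -> DotTrajectories:
    """Derive the "scramble" control stimulus from a walker.

    Dot starting positions are permuted (each trajectory is re-centered
    at another dot's mean position) and each trajectory is re-timed to
    the constant speed equal to its own mean speed, removing the
    acceleration profile while keeping path shapes and per-dot cycle
    frequency intact.
    """
    if walker.n_samples < walker.cycle_length:
        raise ValueError("walker must contain at least one full gait cycle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(walker.n_dots)
    means = walker.positions.mean(axis=1)  # (n_dots, 2)
    out = np.empty_like(walker.positions)
    for k in range(walker.n_dots):
        centered = walker.positions[k] - means[k]
        retimed = _constant_speed_retime(centered + means[k]) - means[k]
        out[k] = retimed + means[perm[k]]
    return DotTrajectories(out, walker.cycle_length)
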