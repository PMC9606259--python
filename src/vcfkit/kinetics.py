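"""Sequential three-state gating kinetics for voltage-sensing domains.

The model describes a voltage sensor moving through three conformations,
Resting (1) <-> Intermediate (2) <-> Activated (3), with no direct 1<->3
pathway.  Each state i carries a free energy ``g_i`` (units of kT, gauge
g_1 = 0) and a gating charge ``q_i`` (elementary charges, gauge q_1 = 0);
each transition i<->j passes through a barrier state ij with its own free
energy ``g_ij`` and charge ``q_ij``.  At membrane potential V the forward
rate out of state i over barrier ij is Eyring-like,

    r_ij(V) = exp(-(dg_ij + dq_ij * V / kT_volts)) / tau,

where dg_ij = g_ij - g_i, dq_ij = q_ij - q_i, kT_volts = k*T/e0 is the
thermal voltage in mV, and tau is the timescale of a barrier-free reaction.
Because forward and backward rates over a transition share the barrier
state, detailed balance holds by construction and the stationary occupancy
at any fixed V is the Boltzmann distribution over (g_i + q_i V / kT_volts).

Depolarisation-activated transitions have negative transferred charge
(dq_ij < 0) under this sign convention, so positive voltages accelerate
activation; this is a convention, not an enforced constraint.

Occupancies under piecewise-constant voltage protocols are propagated per
segment with the exact matrix exponential (via eigendecomposition of the
3x3 generator); an adaptive-ODE path is provided as an independent
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import Boltzmann, elementary_charge
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "KineticModel",
    "VoltageProtocol",
    "OccupancyTrajectory",
    "FluorescenceParameters",
    "transition_rates",
    "rate_matrix",
    "steady_state",
    "propagate",
    "predict_fluorescence",
]

_TRANSITION_NAMES = ("1->2", "2->1", "2->3", "3->2")

# exp() overflows just above 709; rates beyond this are unphysical anyway
_MAX_RATE_EXPONENT = 700.0


def _check_finite(name: str, values) -> None:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {values!r}")


@dataclass(frozen=True)
class KineticModel:
    """Parameters of the sequential three-state gating model.

    Parameters
    ----------
    g_state : tuple of 3 floats
        State free energies (g1, g2, g3) in units of kT; gauge g1 = 0.
    q_state : tuple of 3 floats
        State gating charges (q1, q2, q3) in elementary charges; gauge q1 = 0.
    g_barrier : tuple of 2 floats
        Barrier free energies (g12, g23) in kT for transitions 1<->2, 2<->3.
    q_barrier : tuple of 2 floats
        Barrier charges (q12, q23) in elementary charges.
    tau_ms : float
        Timescale of a barrier-free reaction, ms.
    temperature_K : float
        Absolute temperature; sets the thermal voltage kT/e0.
    """

    g_state: tuple[float, float, float]
    q_state: tuple[float, float, float]
    g_barrier: tuple[float, float]
    q_barrier: tuple[float, float]
    tau_ms: float = 1.0
    temperature_K: float = 293.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "g_state", tuple(float(g) for g in self.g_state))
        object.__setattr__(self, "q_state", tuple(float(q) for q in self.q_state))
        object.__setattr__(self, "g_barrier", tuple(float(g) for g in self.g_barrier))
        object.__setattr__(self, "q_barrier", tuple(float(q) for q in self.q_barrier))
        if len(self.g_state) != 3 or len(self.q_state) != 3:
            raise ValueError("exactly three states are required")
        if len(self.g_barrier) != 2 or len(self.q_barrier) != 2:
            raise ValueError("exactly two transition states are required (1<->2, 2<->3)")
        _check_finite("g_state", self.g_state)
        _check_finite("q_state", self.q_state)
        _check_finite("g_barrier", self.g_barrier)
        _check_finite("q_barrier", self.q_barrier)
        if not (np.isfinite(self.tau_ms) and self.tau_ms > 0):
            raise ValueError(f"tau_ms must be positive and finite, got {self.tau_ms}")
        if not (np.isfinite(self.temperature_K) and self.temperature_K > 0):
            raise ValueError(f"temperature_K must be positive, got {self.temperature_K}")
        if self.g_state[0] != 0.0 or self.q_state[0] != 0.0:
            raise ValueError("gauge requires g_state[0] == 0 and q_state[0] == 0")

    @property
    def kT_volts(self) -> float:
        """Thermal voltage k*T/e0 in mV (~25.26 mV at 293.15 K)."""
        return 1000.0 * Boltzmann * self.temperature_K / elementary_charge


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant voltage-command waveform.

    ``segments`` is an ordered sequence of (duration_ms, voltage_mV); the
    sampling grid is t_k = k * dt_ms from 0 up to the total duration
    (endpoint included when it falls on the grid).  A sample at a segment
    boundary belongs to the *later* segment, so the command at a step onset
    is already the step voltage; the final sample belongs to the last
    segment.
    """

    segments: tuple[tuple[float, float], ...]
    dt_ms: float = 0.5

    def __post_init__(self) -> None:
        segs = tuple((float(d), float(v)) for d, v in self.segments)
        object.__setattr__(self, "segments", segs)
        for d, v in segs:
            if not (np.isfinite(d) and d > 0):
                raise ValueError(f"segment durations must be positive, got {d}")
            if not np.isfinite(v):
                raise ValueError(f"segment voltage must be finite, got {v}")
        if not (np.isfinite(self.dt_ms) and self.dt_ms > 0):
            raise ValueError(f"dt_ms must be positive, got {self.dt_ms}")
        if segs and self.dt_ms > min(d for d, _ in segs) + 1e-12:
            raise ValueError("dt_ms must not exceed the shortest segment duration")

    @property
    def total_duration_ms(self) -> float:
        return float(sum(d for d, _ in self.segments))

    @property
    def boundaries_ms(self) -> np.ndarray:
        """Cumulative segment end times (one entry per segment)."""
        return np.cumsum([d for d, _ in self.segments])

    def times(self) -> np.ndarray:
        total = self.total_duration_ms
        n = int(math.floor(total / self.dt_ms + 1e-9))
        return np.arange(n + 1) * self.dt_ms

    def segment_index(self, t) -> np.ndarray:
        """Segment each time sample falls in (boundary samples -> later segment)."""
        if not self.segments:
            raise ValueError("protocol has no segments")
        bounds = self.boundaries_ms
        idx = np.searchsorted(bounds, np.asarray(t, dtype=float), side="right")
        return np.minimum(idx, len(self.segments) - 1)

    def voltages(self) -> np.ndarray:
        """Command voltage aligned to the sampling grid of :meth:`times`."""
        if not self.segments:
            return np.zeros(1)
        v = np.array([v for _, v in self.segments])
        return v[self.segment_index(self.times())]


@dataclass(frozen=True)
class OccupancyTrajectory:
    """Time-resolved state probabilities on a protocol's sampling grid."""

    t: np.ndarray
    p: np.ndarray  # shape (n_times, 3)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] != t.shape[0]:
            raise ValueError("p must have shape (len(t), 3)")
        sums = p.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > 1e-9:
            raise ValueError("occupancies must sum to 1 within 1e-9 at every sample")
        if np.min(p) < -1e-9 or np.max(p) > 1 + 1e-9:
            raise ValueError("occupancies must lie in [0, 1]")
        # round off integrator wiggle at the boundaries of [0, 1]
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "p", np.clip(p, 0.0, 1.0))


@dataclass(frozen=True)
class FluorescenceParameters:
    """Per-state fluorescence intensities (F1, F2, F3), arbitrary units.

    When fitted, F1 is the gauge (fixed to 1) and F2, F3 are relative
    brightnesses of the intermediate and activated states.
    """

    f_state: tuple[float, float, float]

    def __post_init__(self) -> None:
        fs = tuple(float(f) for f in self.f_state)
        object.__setattr__(self, "f_state", fs)
        if len(fs) != 3:
            raise ValueError("exactly three state fluorescence intensities required")
        _check_finite("f_state", fs)
        if any(f <= 0 for f in fs):
            raise ValueError(f"state fluorescence intensities must be positive, got {fs}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.f_state, dtype=float)


def _rate_exponents(model: KineticModel, V: float) -> np.ndarray:
    """-(dg + dq*V/kT_volts) for transitions (1->2, 2->1, 2->3, 3->2)."""
    g1, g2, g3 = model.g_state
    q1, q2, q3 = model.q_state
    gb12, gb23 = model.g_barrier
    qb12, qb23 = model.q_barrier
    v = float(V) / model.kT_volts
    dg = np.array([gb12 - g1, gb12 - g2, gb23 - g2, gb23 - g3])
    dq = np.array([qb12 - q1, qb12 - q2, qb23 - q2, qb23 - q3])
    return -(dg + dq * v)


def transition_rates(model: KineticModel, V: float) -> np.ndarray:
    """Voltage-dependent rates (r_12, r_21, r_23, r_32) in 1/ms.

    Raises on overflow (exponent > 700); underflow toward rate 0 for very
    high barriers is permitted and represents a frozen transition.
    """
    expo = _rate_exponents(model, V)
    too_big = expo > _MAX_RATE_EXPONENT
    if np.any(too_big):
        bad = _TRANSITION_NAMES[int(np.argmax(too_big))]
        raise OverflowError(
            f"rate for transition {bad} overflows at V={V} mV "
            f"(exponent {expo.max():.1f} > {_MAX_RATE_EXPONENT:g})"
        )
    return np.exp(expo) / model.tau_ms


def rate_matrix(model: KineticModel, V: float) -> np.ndarray:
    """3x3 generator Q(V) with dp/dt = Q p (columns sum to zero).

    Entry Q[j, i] (i != j) is the rate from state i to state j; states 1 and
    3 are never directly coupled.
    """
    r12, r21, r23, r32 = transition_rates(model, V)
    return np.array(
        [
            [-r12, r21, 0.0],
            [r12, -(r21 + r23), r32],
            [0.0, r23, -r32],
        ]
    )


def steady_state(model: KineticModel, V: float) -> np.ndarray:
    """Boltzmann stationary occupancy at fixed voltage.

    p_i is proportional to exp(-(g_i + q_i V / kT_volts)); by detailed
    balance this is also the null vector of :func:`rate_matrix`.
    """
    g = np.asarray(model.g_state)
    q = np.asarray(model.q_state)
    w = -(g + q * float(V) / model.kT_volts)
    w -= w.max()  # overflow-safe normalisation
    p = np.exp(w)
    return p / p.sum()


def _evolve_segment(
    Q: np.ndarray, p0: np.ndarray, t_rel: np.ndarray, eig=None
) -> np.ndarray:
    """Solve dp/dt = Q p at relative times t_rel (exact, eigendecomposition).

    ``eig`` optionally carries a precomputed ``(w, U)`` pair.  Falls back to
    repeated ``expm`` stepping if Q is defective (never the case for a
    detailed-balance generator, but guarded for safety).
    """
    w, U = np.linalg.eig(Q) if eig is None else eig
    try:
        with np.errstate(over="ignore", invalid="ignore", under="ignore"):
            c = np.linalg.solve(U, p0.astype(complex))
            out = np.real((U * c) @ np.exp(np.outer(w, t_rel)))
        # imaginary parts are roundoff for a reversible chain; a defective
        # eigenbasis shows up as broken probability conservation
        if np.all(np.isfinite(out)) and np.max(np.abs(out.sum(axis=0) - 1.0)) < 1e-6:
            return out
    except np.linalg.LinAlgError:
        pass
    # fallback for a (near-)defective eigenbasis
    stiffness = np.max(np.abs(Q)) * (np.max(t_rel) if len(t_rel) else 0.0)
    if stiffness < 200.0:
        out = np.empty((3, len(t_rel)))
        for k, t in enumerate(t_rel):
            out[:, k] = expm(Q * t) @ p0
        return out
    # extremely stiff and defective: every transient mode has decayed on
    # this grid, so samples sit at the segment's stationary distribution
    # (t = 0 keeps the initial condition exactly)
    idx = int(np.argmin(np.abs(w)))
    p_inf = np.real(U[:, idx])
    s = p_inf.sum()
    if not np.isfinite(s) or abs(s) < 1e-300:
        raise FloatingPointError(
            "state propagation failed: generator is numerically degenerate "
            f"(max rate {np.max(np.abs(Q)):.3g}/ms)"
        )
    p_inf = p_inf / s
    out = np.tile(p_inf[:, None], (1, len(t_rel)))
    out[:, t_rel == 0.0] = p0[:, None]
    return out


def _propagate_arrays(
    model: KineticModel, protocol: VoltageProtocol, p0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fast per-segment matrix-exponential propagation (no validation layer)."""
    t = protocol.times()
    seg_of = protocol.segment_index(t)
    bounds = protocol.boundaries_ms
    starts = np.concatenate([[0.0], bounds[:-1]])
    p_out = np.empty((len(t), 3))

    eig_cache: dict[float, tuple] = {}
    p_seg = p0
    for i, (dur, V) in enumerate(protocol.segments):
        if V not in eig_cache:
            Q = rate_matrix(model, V)
            eig_cache[V] = (Q, np.linalg.eig(Q))
        Q, eig = eig_cache[V]
        mask = seg_of == i
        # evaluate sample times and the segment end in one decomposition
        t_eval = np.concatenate([t[mask] - starts[i], [dur]])
        out = _evolve_segment(Q, p_seg, t_eval, eig=eig)
        p_out[mask] = out[:, :-1].T
        p_seg = np.clip(out[:, -1], 0.0, None)
        p_seg = p_seg / p_seg.sum()

    p_out /= p_out.sum(axis=1, keepdims=True)
    return t, p_out


def propagate(
    model: KineticModel,
    protocol: VoltageProtocol,
    p0: np.ndarray | None = None,
    method: str = "expm",
) -> OccupancyTrajectory:
    """Time-resolved occupancies under a piecewise-constant protocol.

    Parameters
    ----------
    p0
        Initial occupancy; defaults to the steady state at the protocol's
        first (holding) voltage, emulating a trace that starts from a stable
        holding fluorescence.
    method
        ``"expm"`` (default): exact per-segment matrix exponential.
        ``"ode"``: adaptive stiff integration (independent cross-check).
    """
    if p0 is None:
        if not protocol.segments:
            raise ValueError("p0 is required for an empty protocol")
        p0 = steady_state(model, protocol.segments[0][1])
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (3,):
        raise ValueError("p0 must be a length-3 occupancy vector")
    if abs(p0.sum() - 1.0) > 1e-9 or np.any(p0 < -1e-12):
        raise ValueError("p0 must be a probability vector summing to 1")

    if not protocol.segments:
        return OccupancyTrajectory(t=np.zeros(1), p=p0[None, :].copy())

    t = protocol.times()
    seg_of = protocol.segment_index(t)
    bounds = protocol.boundaries_ms
    starts = np.concatenate([[0.0], bounds[:-1]])
    p_out = np.empty((len(t), 3))

    if method not in ("expm", "ode"):
        raise ValueError(f"unknown propagation method {method!r}")

    if method == "expm":
        t, p = _propagate_arrays(model, protocol, p0)
        return OccupancyTrajectory(t=t, p=p)

    p_seg = p0
    for i, (dur, V) in enumerate(protocol.segments):
        mask = seg_of == i
        # include the segment end so the carry-over state is exact
        t_rel = t[mask] - starts[i]
        if len(t_rel) and abs(t_rel[-1] - dur) < 1e-12:
            t_eval, has_end = t_rel, True
        else:
            t_eval, has_end = np.concatenate([t_rel, [dur]]), False
        Q = rate_matrix(model, V)
        sol = solve_ivp(
            lambda _t, p: Q @ p,
            (0.0, dur),
            p_seg,
            method="LSODA",
            t_eval=t_eval,
            rtol=1e-10,
            atol=1e-12,
            jac=lambda _t, _p: Q,
        )
        if not sol.success:
            raise RuntimeError(
                "stiff integration failed for segment "
                f"{i} (V={V} mV): {sol.message}; use method='expm' "
                "(exact matrix exponential) instead"
            )
        p_out[mask] = sol.y.T if has_end else sol.y[:, :-1].T
        p_seg = sol.y[:, -1]
        # renormalise roundoff drift; conservation is exact in theory
        p_seg = np.clip(p_seg, 0.0, None)
        p_seg = p_seg / p_seg.sum()

    row_sums = p_out.sum(axis=1, keepdims=True)
    p_out = p_out / row_sums
    return OccupancyTrajectory(t=t, p=p_out)


def predict_fluorescence(
    traj: OccupancyTrajectory, fp: FluorescenceParameters
) -> np.ndarray:
    """Macroscopic fluorescence F(t) = sum_i P_i(t) F_i on the trajectory grid."""
    return traj.p @ fp.as_array()
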