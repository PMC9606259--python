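"""Trace-level VCF signal metrics.

Quantities extracted from a single fluorescence sweep recorded under a
voltage-step protocol: the baseline F_h at the holding potential, the four
signed deflections dF_peak / dF_ss / dF_tail / dF_hook (and their
percent-of-F_h forms), photobleaching correction from a constant-voltage
baseline sweep, Boxcar smoothing, normalised F-V and G-V curves, the fast
activation time constant used to exclude an electrochromic (Stark-shift)
origin of the signal, and the absorbance-based attenuation fraction for
lipid-vesicle experiments.

Sign convention: the dye signals here are negative-going on depolarisation,
so "peaks" are minima and all dF values are signed (typically negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "VcfTrace",
    "DeltaFMetrics",
    "AbsorbanceReading",
    "CurveXY",
    "BleachFit",
    "FastComponentFit",
    "boxcar_filter",
    "photobleach_correct",
    "compute_delta_f",
    "fv_curve",
    "gv_curve",
    "fit_fast_component",
    "attenuation_fraction",
]


@dataclass(frozen=True)
class VcfTrace:
    """One fluorescence (and optionally current) sweep on a uniform time grid.

    Fields: ``t`` in ms (strictly increasing, uniform), ``F`` fluorescence in
    arbitrary units, ``V`` command voltage in mV aligned to ``t``, optional
    ``I`` current in uA, and free-form ``meta`` (construct label, holding
    voltage, sampling rate, seed, step window...).
    """

    t: np.ndarray
    F: np.ndarray
    V: np.ndarray
    I: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        F = np.asarray(self.F, dtype=float)
        V = np.asarray(self.V, dtype=float)
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("t must be a non-empty 1-d array")
        if F.shape != t.shape or V.shape != t.shape:
            raise ValueError("F and V must be aligned with t")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0):
                raise ValueError("time grid must be uniformly spaced")
        if not np.all(np.isfinite(F)):
            raise ValueError("fluorescence must be finite")
        I = self.I
        if I is not None:
            I = np.asarray(I, dtype=float)
            if I.shape != t.shape:
                raise ValueError("I must be aligned with t")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "I", I)

    @property
    def dt_ms(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan

    @property
    def sampling_hz(self) -> float:
        return 1000.0 / self.dt_ms


@dataclass(frozen=True)
class DeltaFMetrics:
    """The four signed dF values of one sweep, absolute and as % of F_h.

    dF_peak: deepest (negative-going) deflection during the step.
    dF_ss:   level at the end of the step, relative to F_h.
    dF_tail: deepest deflection after repolarisation.
    dF_hook: dF_tail - dF_ss (the repolarisation undershoot), exact.
    """

    F_h: float
    dF_peak: float
    dF_ss: float
    dF_tail: float

    @property
    def dF_hook(self) -> float:
        return self.dF_tail - self.dF_ss

    @property
    def dF_peak_pct(self) -> float:
        return 100.0 * self.dF_peak / self.F_h

    @property
    def dF_ss_pct(self) -> float:
        return 100.0 * self.dF_ss / self.F_h

    @property
    def dF_tail_pct(self) -> float:
        return 100.0 * self.dF_tail / self.F_h

    @property
    def dF_hook_pct(self) -> float:
        return 100.0 * self.dF_hook / self.F_h

    def value(self, which: str, percent: bool = False) -> float:
        key = {"peak": "dF_peak", "ss": "dF_ss", "tail": "dF_tail", "hook": "dF_hook"}
        if which not in key:
            raise ValueError(f"unknown metric selector {which!r}; use peak/ss/tail/hook")
        return getattr(self, key[which] + ("_pct" if percent else ""))


@dataclass(frozen=True)
class AbsorbanceReading:
    """Solution absorbance at TAMRA's excitation (540 nm) and emission (565 nm) maxima."""

    A540: float
    A565: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A540) and np.isfinite(self.A565)):
            raise ValueError("absorbances must be finite")
        if self.A540 < 0 or self.A565 < 0:
            raise ValueError(f"absorbances must be >= 0, got ({self.A540}, {self.A565})")


@dataclass(frozen=True)
class CurveXY:
    """Normalised amplitude versus test potential (F-V or G-V curve)."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if len(y) and abs(np.max(np.abs(y)) - 1.0) > 1e-9:
            raise ValueError("normalized curve must satisfy max |y| = 1")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class BleachFit:
    """Exponential baseline fit F(t) ~ C + B exp(-t / tau_b)."""

    B: float
    tau_b_ms: float
    C: float
    residual_rms: float


@dataclass(frozen=True)
class FastComponentFit:
    """Single-exponential fit to the initial fluorescence change of a step."""

    tau_ms: float
    amplitude: float
    residual_rms: float
    identifiable: bool = True


def boxcar_filter(trace: VcfTrace, points: int = 3) -> VcfTrace:
    """Centered moving-average (Boxcar) smoothing of the fluorescence channel.

    ``points`` must be odd; windows shrink symmetrically at the edges so the
    length is preserved.  Voltage and current channels are untouched.
    """
    points = int(points)
    if points < 1 or points % 2 == 0:
        raise ValueError(f"points must be an odd integer >= 1, got {points}")
    if points == 1:
        return trace
    half = points // 2
    F = trace.F
    n = len(F)
    csum = np.concatenate([[0.0], np.cumsum(F)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return replace(trace, F=smoothed)


def photobleach_correct(
    trace: VcfTrace, baseline: VcfTrace
) -> tuple[VcfTrace, BleachFit]:
    """Remove slow photobleaching using a constant-voltage baseline sweep.

    The baseline (no voltage change, hence no gating signal) is fitted with
    F(t) ~ C + B exp(-t/tau_b); the decaying component B*(exp(-t/tau_b) - 1)
    is then subtracted from the trace, leaving its t = 0 value unchanged.
    A genuinely flat baseline yields B ~ 0 and an identity correction.
    """
    if abs(baseline.dt_ms - trace.dt_ms) > 1e-9 * trace.dt_ms:
        raise ValueError("baseline and trace must share the sampling interval")
    if np.ptp(baseline.V) > 1e-9:
        raise ValueError("baseline sweep must be recorded at constant voltage")

    tb = baseline.t - baseline.t[0]
    Fb = baseline.F
    span = tb[-1] - tb[0] if len(tb) > 1 else 1.0
    scale = max(np.ptp(Fb), 1e-30)
    flat_tol = 1e-6 * max(abs(np.mean(Fb)), 1.0)

    def model(t, C, B, tau):
        return C + B * np.exp(-t / tau)

    fit_ok = False
    if np.ptp(Fb) > flat_tol:
        p0 = (Fb[-1], Fb[0] - Fb[-1], span / 3.0)
        try:
            popt, _ = curve_fit(
                model,
                tb,
                Fb,
                p0=p0,
                bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            C, B, tau_b = popt
            fit_ok = np.isfinite(popt).all() and tau_b > 0
        except RuntimeError:
            fit_ok = False
    if not fit_ok:
        # flat or unresolvable decay: only accept the identity correction
        # when the baseline really carries no trend beyond its scatter
        slope = np.polyfit(tb, Fb, 1)[0] if len(tb) > 1 else 0.0
        scatter = np.std(Fb - np.polyval(np.polyfit(tb, Fb, 1), tb)) if len(tb) > 2 else 0.0
        if abs(slope) * span > max(5.0 * scatter, flat_tol):
            raise RuntimeError(
                "photobleach baseline fit failed to converge on a trending "
                f"baseline (slope*span={slope * span:.3g}, scatter={scatter:.3g})"
            )
        C, B, tau_b = float(np.mean(Fb)), 0.0, np.inf
    resid = Fb - model(tb, C, B, tau_b) if np.isfinite(tau_b) else Fb - C
    info = BleachFit(B=float(B), tau_b_ms=float(tau_b), C=float(C),
                     residual_rms=float(np.sqrt(np.mean(resid**2))))

    tt = trace.t - trace.t[0]
    decay = B * (np.exp(-tt / tau_b) - 1.0) if np.isfinite(tau_b) else np.zeros_like(tt)
    corrected = replace(trace, F=trace.F - decay)
    return corrected, info


def compute_delta_f(
    trace: VcfTrace,
    step_window: tuple[float, float],
    f_h_window_ms: float = 100.0,
    ss_fraction: float = 0.05,
    smooth_points: int = 3,
) -> DeltaFMetrics:
    """Extract F_h and the four dF metrics from one sweep.

    Parameters
    ----------
    step_window
        (t_on, t_off) of the depolarising step in ms.
    f_h_window_ms
        Length of the pre-step window whose mean defines F_h.
    ss_fraction
        Fraction of the step (at its end) averaged for dF_ss.
    smooth_points
        Boxcar width applied before extremum detection (the recording
        convention for these signals); the raw trace is left untouched.
    """
    t_on, t_off = float(step_window[0]), float(step_window[1])
    t = trace.t
    if not (t[0] <= t_on < t_off <= t[-1]):
        raise ValueError(
            f"step_window ({t_on}, {t_off}) must lie inside the trace "
            f"[{t[0]}, {t[-1]}] with t_on < t_off"
        )
    if t_on <= t[0]:
        raise ValueError("a pre-step segment is required to estimate F_h")

    F = boxcar_filter(trace, smooth_points).F

    pre = (t >= max(t[0], t_on - f_h_window_ms)) & (t < t_on)
    F_h = float(np.mean(F[pre]))
    if F_h <= 0:
        raise ValueError(f"baseline fluorescence F_h must be positive, got {F_h}")

    step = (t >= t_on) & (t < t_off)
    dF_peak = float(np.min(F[step]) - F_h)

    ss = (t >= t_off - ss_fraction * (t_off - t_on)) & (t < t_off)
    dF_ss = float(np.mean(F[ss]) - F_h)

    post = t >= t_off
    dF_tail = float(np.min(F[post]) - F_h)

    return DeltaFMetrics(F_h=F_h, dF_peak=dF_peak, dF_ss=dF_ss, dF_tail=dF_tail)


def fv_curve(
    metrics_by_voltage: list[tuple[float, DeltaFMetrics]], which: str = "tail"
) -> CurveXY:
    """Fluorescence-voltage relation for one dF metric, normalised to max |dF/F_h|.

    The sign of the (typically negative-going) signal is preserved, so the
    deepest point maps to -1 for quenching signals.
    """
    if len(metrics_by_voltage) < 2:
        raise ValueError("at least two test potentials are required for an F-V curve")
    x = np.array([v for v, _ in metrics_by_voltage], dtype=float)
    y = np.array([m.value(which, percent=True) for _, m in metrics_by_voltage])
    peak = np.max(np.abs(y))
    if peak == 0:
        raise ValueError("all dF values are zero; F-V normalization is undefined")
    return CurveXY(x=x, y=y / peak, label=f"dF_{which}/F_h")


def gv_curve(
    current_traces: list[VcfTrace],
    step_window: tuple[float, float],
    leak_potentials: list[float],
    tail_window_ms: float = 50.0,
    settle_samples: int = 2,
    zero_tol: float = 1e-9,
) -> CurveXY:
    """Conductance-voltage relation from leak-corrected tail currents.

    An ohmic leak I = a + b V is fitted to the step-window currents of the
    designated sub-activation sweeps (``leak_potentials``, matched to each
    trace's step voltage) plus the pre-step holding currents, subtracted
    from every trace, and the tail amplitude is the mean corrected current
    over ``tail_window_ms`` after repolarisation (skipping
    ``settle_samples`` clamp-settling points).  Output normalised to max 1.
    """
    t_on, t_off = float(step_window[0]), float(step_window[1])
    if not leak_potentials:
        raise ValueError("leak correction requires designated sub-activation sweeps")

    steps, tails, leak_pts = [], [], []
    for tr in current_traces:
        if tr.I is None:
            raise ValueError("G-V construction requires a current channel on every trace")
        t = tr.t
        step = (t >= t_on) & (t < t_off)
        v_step = float(np.median(tr.V[step]))
        pre = t < t_on
        leak_pts.append((float(np.median(tr.V[pre])), float(np.mean(tr.I[pre]))))
        # use the late half of the step so capacitive/gating transients settle
        late = (t >= t_on + 0.5 * (t_off - t_on)) & (t < t_off)
        if any(abs(v_step - lv) < 1e-6 for lv in leak_potentials):
            leak_pts.append((v_step, float(np.mean(tr.I[late]))))
        steps.append(v_step)
        i0 = int(np.searchsorted(t, t_off)) + settle_samples
        i1 = int(np.searchsorted(t, t_off + tail_window_ms))
        if i0 >= len(t):
            raise ValueError("tail window lies outside the trace")
        tails.append((tr, i0, max(i1, i0 + 1)))

    lv = np.array([v for v, _ in leak_pts])
    li = np.array([i for _, i in leak_pts])
    if np.ptp(lv) < 1e-9:
        raise ValueError("leak sweeps span a single voltage; cannot fit an ohmic leak")
    b, a = np.polyfit(lv, li, 1)

    amps = []
    for tr, i0, i1 in tails:
        i_corr = tr.I[i0:i1] - (a + b * tr.V[i0:i1])
        amps.append(float(np.mean(i_corr)))
    amps = np.array(amps)
    peak = np.max(np.abs(amps))
    if peak <= zero_tol:
        raise ValueError(
            "all leak-corrected tail currents are zero within tolerance; "
            "G-V normalization is undefined"
        )
    return CurveXY(x=np.array(steps), y=amps / peak, label="G/G_max")


def fit_fast_component(
    trace: VcfTrace, window: tuple[float, float], smooth_points: int = 1
) -> FastComponentFit:
    """Time constant of the initial fluorescence change after a voltage step.

    Fits F(t) ~ C + A exp(-(t - t_start)/tau) over ``window`` (which should
    begin at the depolarisation onset).  Comparing the fitted tau with the
    clamp speed distinguishes conformational signals from an electrochromic
    (Stark) effect, whose kinetics match the clamp.  A flat window is
    reported with amplitude ~ 0 and ``identifiable=False``.
    """
    t0, t1 = float(window[0]), float(window[1])
    t = trace.t
    mask = (t >= t0) & (t <= t1)
    if mask.sum() < 4:
        raise ValueError("fast-component window must contain at least 4 samples")
    F = boxcar_filter(trace, smooth_points).F[mask] if smooth_points > 1 else trace.F[mask]
    tt = t[mask] - t0

    scatter = float(np.std(np.diff(F))) / np.sqrt(2.0)
    if np.ptp(F) <= max(3.0 * scatter, 1e-12 * max(abs(F[0]), 1.0)):
        return FastComponentFit(
            tau_ms=np.nan, amplitude=0.0,
            residual_rms=float(np.std(F)), identifiable=False,
        )

    def model(x, C, A, tau):
        return C + A * np.exp(-x / tau)

    p0 = (F[-1], F[0] - F[-1], max((t1 - t0) / 5.0, trace.dt_ms))
    try:
        popt, _ = curve_fit(
            model, tt, F, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"fast-component exponential fit did not converge: {exc}")
    C, A, tau = popt
    resid = F - model(tt, *popt)
    return FastComponentFit(
        tau_ms=float(tau), amplitude=float(A),
        residual_rms=float(np.sqrt(np.mean(resid**2))), identifiable=True,
    )


def attenuation_fraction(a: AbsorbanceReading) -> float:
    """Fractional loss of detected fluorescence from solution absorbance.

    Excitation light is attenuated by 10^-A540 and emitted light by
    10^-A565, so the detected signal falls by 1 - 10^-A540 * 10^-A565.
    Monotone in each absorbance and bounded in [0, 1).
    """
    return 1.0 - 10.0 ** (-a.A540) * 10.0 ** (-a.A565)
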