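"""Synthetic VCF data generation.

Emulates the experimental conditions of the study this package models:
2 kHz-sampled fluorescence sweeps from a holding potential of -60 mV with
1-s steps to {-60, -20, +20, +60, +100} mV, negative-going dF/F_h signals
of a few percent, additive Gaussian noise, slow exponential photobleaching,
optional ohmic-leak proton current, and optional absorbance attenuation by
extracellular lipid vesicles.

Three construct-class presets share one kinetic model and differ only in
their per-state fluorescence intensities:

``no-quencher``
    F3 > F1 > F2 — biphasic signal with a repolarisation hook; the
    macroscopic level at step end recovers to just below baseline (the slow
    2->3 transition has not fully equilibrated within the 1-s step).
``weak-quencher``
    F1 > F3 > F2 — biphasic, partial recovery well below baseline.
``strong-quencher``
    F1 > F2 > F3 — monotonic decay; strong quenching overrides the lipid
    environment effect.

Also provides the binomial heterodimer-composition calculator used to
argue that, at 20% labeled RNA, ~89% of signal-competent dimers carry
exactly one dye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (
    FluorescenceParameters,
    KineticModel,
    OccupancyTrajectory,
    VoltageProtocol,
    predict_fluorescence,
    propagate,
    steady_state,
)
from .metrics import AbsorbanceReading, VcfTrace, attenuation_fraction

__all__ = [
    "SyntheticScenario",
    "DimerComposition",
    "PRESET_KINETICS",
    "PRESET_FLUORESCENCE",
    "CONSTRUCT_CLASSES",
    "preset_scenario",
    "make_step_protocol",
    "make_baseline_protocol",
    "generate_trace",
    "generate_baseline",
    "heterodimer_fractions",
    "apply_pc_attenuation",
]

CONSTRUCT_CLASSES = ("no-quencher", "weak-quencher", "strong-quencher")

# One shared kinetic parameter set for all construct classes (the constructs
# gate alike; only the dye's photophysics differs).  Rates at +100 mV:
# 1->2 ~ 1/ms (fast component), 2->3 ~ 1/600 ms (slow component, still
# relaxing at the end of a 1-s step).  At -60 mV: 3->2 ~ 1/20 ms (hook
# downstroke), 2->1 ~ 1/50 ms (slow recovery).
PRESET_KINETICS = KineticModel(
    g_state=(0.0, 1.0, 2.0),
    q_state=(0.0, -1.5, -3.0),
    g_barrier=(5.29, 8.13),
    q_barrier=(-1.34, -1.68),
    tau_ms=1.0,
    temperature_K=293.15,
)

# Relative state brightnesses (F1 = 1 gauge); chosen to reproduce the three
# qualitative signal classes with dF/F_h amplitudes of a few percent.
PRESET_FLUORESCENCE = {
    "no-quencher": FluorescenceParameters((1.0, 0.955, 1.005)),
    "weak-quencher": FluorescenceParameters((1.0, 0.955, 0.985)),
    "strong-quencher": FluorescenceParameters((1.0, 0.975, 0.945)),
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground truth and nuisance parameters for one simulated sweep.

    noise_sd is the additive Gaussian noise SD as a fraction of F_h;
    bleach follows F(t) * [(1 - a) + a exp(-t/tau_b)] with amplitude
    fraction a and time constant tau_b.
    """

    construct: str
    model: KineticModel
    fluorescence: FluorescenceParameters
    protocol: VoltageProtocol
    noise_sd: float = 0.001
    bleach_fraction: float = 0.05
    bleach_tau_ms: float = 20_000.0
    absorbance: AbsorbanceReading | None = None
    seed: int = 0
    include_current: bool = False
    gmax: float = 5.0          # uA at unit open probability and 100 mV driving force
    e_rev_mV: float = -40.0    # proton reversal potential under the recording gradient
    leak_g: float = 0.002      # uA/mV ohmic leak slope
    leak_e_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.bleach_fraction < 1):
            raise ValueError("bleach_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class DimerComposition:
    """Binomial composition of dimers at a given labeled-subunit fraction.

    ``singly_labeled_share`` is the fraction of signal-competent dimers
    (those with at least one dye) that carry exactly one; NaN at f = 0
    where no dimer carries a dye.
    """

    labeled_fraction: float
    p_both: float
    p_single: float
    p_none: float
    singly_labeled_share: float

    def __post_init__(self) -> None:
        total = self.p_both + self.p_single + self.p_none
        if abs(total - 1.0) > 1e-12:
            raise ValueError("dimer probabilities must sum to 1")


def make_step_protocol(
    holding_mV: float = -60.0,
    test_mV: tuple[float, ...] = (-60.0, -20.0, 20.0, 60.0, 100.0),
    step_ms: float = 1000.0,
    pre_ms: float = 100.0,
    post_ms: float = 300.0,
    dt_ms: float = 0.5,
) -> list[VoltageProtocol]:
    """One holding/step/holding protocol per test potential (2 kHz default)."""
    if step_ms <= 0 or pre_ms <= 0 or post_ms <= 0:
        raise ValueError("durations must be positive")
    return [
        VoltageProtocol(
            segments=((pre_ms, holding_mV), (step_ms, v), (post_ms, holding_mV)),
            dt_ms=dt_ms,
        )
        for v in test_mV
    ]


def make_baseline_protocol(protocol: VoltageProtocol) -> VoltageProtocol:
    """Constant-voltage protocol of equal duration (for bleach fitting)."""
    hold = protocol.segments[0][1]
    return VoltageProtocol(
        segments=((protocol.total_duration_ms, hold),), dt_ms=protocol.dt_ms
    )


def preset_scenario(
    construct: str,
    protocol: VoltageProtocol,
    noise_sd: float = 0.001,
    bleach_fraction: float = 0.05,
    bleach_tau_ms: float = 20_000.0,
    seed: int = 0,
    **kwargs,
) -> SyntheticScenario:
    """Scenario for one of the three construct-class presets."""
    if construct not in PRESET_FLUORESCENCE:
        raise ValueError(
            f"unknown construct class {construct!r}; choose from {CONSTRUCT_CLASSES}"
        )
    return SyntheticScenario(
        construct=construct,
        model=PRESET_KINETICS,
        fluorescence=PRESET_FLUORESCENCE[construct],
        protocol=protocol,
        noise_sd=noise_sd,
        bleach_fraction=bleach_fraction,
        bleach_tau_ms=bleach_tau_ms,
        seed=seed,
        **kwargs,
    )


def _step_window(protocol: VoltageProtocol) -> tuple[float, float] | None:
    if len(protocol.segments) == 3:
        b = protocol.boundaries_ms
        return float(b[0]), float(b[1])
    return None


def generate_trace(s: SyntheticScenario) -> tuple[VcfTrace, dict]:
    """Simulate one sweep; returns the trace and a ground-truth record.

    The occupancies start from the holding-voltage steady state; the clean
    fluorescence sum(P_i F_i) is multiplied by the bleach exponential and
    the attenuation factor, then Gaussian noise (SD = noise_sd * F_h) is
    added.  Fully reproducible from the scenario seed.
    """
    traj = propagate(s.model, s.protocol)
    f_clean = predict_fluorescence(traj, s.fluorescence)
    p_hold = steady_state(s.model, s.protocol.segments[0][1])
    f_h = float(p_hold @ s.fluorescence.as_array())

    t = traj.t
    a = s.bleach_fraction
    bleach = (1.0 - a) + a * np.exp(-t / s.bleach_tau_ms) if a > 0 else np.ones_like(t)
    scale = 1.0
    if s.absorbance is not None:
        scale = 1.0 - attenuation_fraction(s.absorbance)
    rng = np.random.default_rng(s.seed)
    noise = rng.normal(0.0, s.noise_sd * f_h, size=t.shape) if s.noise_sd > 0 else 0.0
    F = f_clean * bleach * scale + noise

    V = s.protocol.voltages()
    I = None
    if s.include_current:
        # open probability taken as the activated-state occupancy p3
        i_channel = s.gmax * traj.p[:, 2] * (V - s.e_rev_mV) / 100.0
        i_leak = s.leak_g * (V - s.leak_e_mV)
        i_noise = rng.normal(0.0, 0.002, size=t.shape) if s.noise_sd > 0 else 0.0
        I = i_channel + i_leak + i_noise

    meta = {
        "construct": s.construct,
        "holding_mV": float(s.protocol.segments[0][1]),
        "sampling_Hz": 1000.0 / s.protocol.dt_ms,
        "seed": int(s.seed),
    }
    sw = _step_window(s.protocol)
    if sw is not None:
        meta["t_on_ms"], meta["t_off_ms"] = sw
        meta["test_mV"] = float(s.protocol.segments[1][1])

    truth = {
        "model": s.model,
        "fluorescence": s.fluorescence,
        "trajectory": traj,
        "F_clean": f_clean,
        "F_h": f_h,
        "bleach": np.asarray(bleach) * np.ones_like(t),
        "attenuation_scale": scale,
    }
    return VcfTrace(t=t, F=F, V=V, I=I, meta=meta), truth


def generate_baseline(s: SyntheticScenario, seed_offset: int = 1_000_003) -> VcfTrace:
    """Constant-voltage companion sweep (bleach + noise only, no gating signal)."""
    base = SyntheticScenario(
        construct=s.construct,
        model=s.model,
        fluorescence=s.fluorescence,
        protocol=make_baseline_protocol(s.protocol),
        noise_sd=s.noise_sd,
        bleach_fraction=s.bleach_fraction,
        bleach_tau_ms=s.bleach_tau_ms,
        absorbance=s.absorbance,
        seed=(s.seed + seed_offset) % (2**31),
    )
    trace, _ = generate_trace(base)
    return trace


def heterodimer_fractions(labeled_fraction: float) -> DimerComposition:
    """Binomial dimer composition at labeled-subunit fraction f.

    Under independent random dimerisation: both labeled with probability
    f^2, exactly one with 2f(1-f), none with (1-f)^2.  Dimers with no dye
    produce no VCF signal, so the share of signal-competent dimers that are
    singly labeled is 2f(1-f) / (1 - (1-f)^2).  At f = 0.2 this is 8/9 ~
    88.9% — the basis of the heterodimer labeling argument.
    """
    f = float(labeled_fraction)
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"labeled_fraction must lie in [0, 1], got {f}")
    p_both = f * f
    p_single = 2.0 * f * (1.0 - f)
    p_none = (1.0 - f) ** 2
    competent = 1.0 - p_none
    share = p_single / competent if competent > 0 else float("nan")
    return DimerComposition(
        labeled_fraction=f,
        p_both=p_both,
        p_single=p_single,
        p_none=p_none,
        singly_labeled_share=share,
    )


def apply_pc_attenuation(trace: VcfTrace, a: AbsorbanceReading) -> VcfTrace:
    """Scale fluorescence by the lipid-absorbance transmission factor.

    Multiplies F by 10^-(A540+A565) = 1 - attenuation_fraction(a).  All
    normalised quantities (dF/F_h, F-V shapes) are invariant; only the
    absolute F_h drops — attenuation dims the signal without reshaping it.
    """
    factor = 1.0 - attenuation_fraction(a)
    from dataclasses import replace

    return replace(trace, F=trace.F * factor)
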