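# Methods

## The signal and the model

Voltage-clamp fluorometry (VCF) records the fluorescence of a dye attached
to a channel's voltage-sensing domain (VSD) while the membrane potential is
stepped. For the Hv1 proton channel labeled at the S3–S4 loop (E241C with a
TAMRA-class dye), the signal is a small negative-going deflection, ΔF/F_h of
a few percent, whose shape depends on the local photophysical environment:
nearby quenching residues (His weakly, Trp strongly) and the dye's partition
between lipid and aqueous phases.

`vcfkit` models gating as a sequential three-state Markov scheme

    Resting (1)  ⇄  Intermediate (2)  ⇄  Activated (3)

with no direct 1↔3 pathway. State *i* carries a free energy `g_i` (units of
kT, gauge `g_1 = 0`) and a gating charge `q_i` (elementary charges, gauge
`q_1 = 0`). Each transition passes through a barrier state *ij* with its own
`g_ij`, `q_ij`, giving Eyring-type voltage-dependent rates

    r_ij(V) = exp(−(Δg_ij + Δq_ij·V / kT_volts)) / τ,

where `Δg_ij = g_ij − g_i`, `Δq_ij = q_ij − q_i`, `kT_volts = kT/e0` is the
thermal voltage in mV, and τ is the barrier-free timescale. Because forward
and backward rates share the barrier state, detailed balance holds by
construction: the stationary distribution at any fixed voltage is the
Boltzmann distribution over `g_i + q_i·V/kT_volts`, and we test this
identity against the numerical null space of the generator.

The observed fluorescence is the occupancy-weighted sum `F(t) = Σ P_i(t)F_i`
of per-state intensities `F1, F2, F3`. The qualitative signal classes map
onto orderings of these intensities:

| class | ordering | trace shape |
|---|---|---|
| no quencher | F3 > F1 > F2 | biphasic, hook, near-full recovery at step end |
| weak quencher | F1 > F3 > F2 | biphasic, hook, partial recovery |
| strong quencher | F1 > F2 > F3 | monotonic decay |

## Units and conventions

Energies in kT (dimensionless), charges in e0, voltages in mV, times in ms.
Default temperature 293.15 K (`kT_volts ≈ 25.26 mV`), a room-temperature
convention. Depolarisation-activated transitions have `Δq_ij < 0` under this
rate law (positive voltage then accelerates activation); this is documented,
not enforced. The rate-matrix convention is `dp/dt = Q p` with columns
summing to zero. An exponent above 700 in any rate raises an error naming
the transition (the rate would overflow); underflow toward a zero rate is
permitted — it represents a frozen transition, and the two-state
closed-form test exploits it.

## Propagation

Protocols are piecewise-constant, so occupancies are propagated exactly per
segment via the eigendecomposition of the 3×3 generator (equivalent to the
matrix exponential; a reversible generator has a real eigensystem). An
adaptive stiff ODE route (`LSODA`, rtol 1e−10) is kept solely as an
independent cross-check; the two routes agree to < 1e−6 on randomized
model/protocol pairs. Unless given, the initial condition is the steady
state at the protocol's first (holding) voltage — traces start from a
stable holding fluorescence. For numerically degenerate eigenbases the code
falls back to direct `expm` stepping, or, when the generator is so stiff
that every transient has decayed between samples, to the segment's
stationary distribution.

## Trace metrics

Following the recording conventions of this preparation (2 kHz sampling,
3-point Boxcar smoothing before extremum detection):

- `F_h`: mean fluorescence over the final 100 ms before the step onset (the
  definition fixes only "fluorescence at holding"; the window length is our
  choice).
- `ΔF_peak`: most negative deflection during the step; `ΔF_ss`: mean over
  the final 5% of the step minus F_h; `ΔF_tail`: most negative deflection
  after repolarisation; `ΔF_hook = ΔF_tail − ΔF_ss`, exact by construction.
- Photobleaching: a companion constant-voltage sweep is fitted with
  `C + B·exp(−t/τ_b)` and the decaying component `B(exp(−t/τ_b) − 1)` is
  subtracted, leaving the t = 0 value unchanged. Subtraction (not division)
  preserves ΔF in absolute units; because bleaching is slow (τ_b ≈ 20 s vs
  1-s sweeps), the residual error of the subtractive operator on a
  multiplicatively bleached signal is second order (≤ 0.02% of F_h for the
  default generator settings).
- F-V curves: the selected ΔF/F_h metric normalised by its maximum absolute
  value, sign preserved (these signals are negative-going).
- G-V curves: mean leak-corrected tail current after repolarisation
  (first 2 samples skipped for clamp settling; 50-ms window), with an ohmic
  leak `I = a + bV` fitted to designated sub-activation sweeps plus the
  pre-step holding currents, normalised to the maximum.
- Fast component: a single exponential fitted at the depolarisation onset;
  its time constant is what distinguishes a conformational signal
  (milliseconds) from an electrochromic artifact (which must match the
  sub-millisecond clamp speed). A flat window is flagged unidentifiable
  rather than fitted.
- Lipid attenuation: absorbance at the dye's excitation/emission maxima
  reduces detected fluorescence by `1 − 10^(−A540)·10^(−A565)`; this scales
  F_h but cancels in every ΔF/F_h quantity.

## Fitting

`ThreeStateTraceFitter` minimises the summed squared difference between
measured and predicted ΔF/F_h over a family of sweeps (scipy
`least_squares`, trust-region reflective, bounded). ΔF/F_h — not raw
fluorescence — is fitted because per-cell expression and background make
absolute amplitudes incomparable across recordings.

Identifiability gauge: `g_1 = q_1 = 0`, `F1 = 1` per construct, τ fixed at
1 ms. Adding a constant *c* to both barrier energies while rescaling
τ → τ·e^(−c) leaves every rate unchanged (asserted numerically), so τ
carries no information beyond the barrier heights. Bounds: |g| ≤ 25 kT,
|q| ≤ 6 e0, `F_i ∈ (0, 10]` — wide but overflow-safe.

Constructs may share one kinetic parameter set (the default, reflecting the
assumption that the mutations alter photophysics, not gating) with
per-construct `F2, F3`; a per-construct kinetic relaxation is available.

Global search: a deterministic center start describing the generic regime
of these signals — resting state favoured at holding, fast 1→2 and slower
2→3 on depolarisation — with `F2, F3` seeded from the observed peak and
step-end deflections (a moment-style guess), plus Latin-hypercube random
starts. All starts are screened with a cheap pass (40 iterations on 4×
time-decimated traces), and the most promising basins plus the center are
polished on the full data. Per-start objectives are reported on the full
data so the best-of-starts invariant is well defined. The model has a
genuine near-degeneracy at realistic noise — a brighter activated state
with partial activation can mimic a dimmer one with full activation — which
is why the multi-start layer, not the local optimizer, decides success.

## Synthetic data

The generator emulates the study conditions: 2 kHz sampling, holding
−60 mV, 1-s steps to {−60, −20, +20, +60, +100} mV with 100 ms pre- and
300 ms post-step holding, additive white Gaussian noise with SD expressed
as a fraction of F_h (default 0.1%), multiplicative exponential
photobleaching toward a plateau (default 5% amplitude, τ_b = 20 s), an
optional proton-current channel (open probability taken as p3, ohmic leak),
and optional absorbance attenuation.

The three construct-class presets share one kinetic model (at +100 mV:
1→2 ≈ 1/ms, 2→3 ≈ 1/600 ms; at −60 mV: 3→2 ≈ 1/20 ms, 2→1 ≈ 1/50 ms) and
differ only in `F_state`. The slow second transition deliberately leaves
~19% intermediate occupancy at the end of a 1-s step: for the no-quencher
class this makes the macroscopic step-end level settle just *below*
baseline (ΔF_ss ≈ −0.5%) even though F3 > F1 — the microscopic brightness
of the activated state exceeds resting while the population average has not
caught up, which is exactly the regime these signals occupy. The preset
parameter values are artifact choices that realise the documented
orderings and shapes; they are not estimates of any particular recording.

What the generator does *not* emulate: correlated (1/f or shot) noise,
clamp settling transients, series-resistance artifacts, dye bleaching that
depends on fluorescence level, or cell-to-cell parameter heterogeneity.
Passing tests therefore demonstrate correctness of the estimators under
idealised white-noise conditions, not robustness to every instrumental
artifact.

## Numerical choices and degenerate inputs

- Occupancy conservation is enforced to 1e−9 and roundoff is renormalised.
- A protocol with no segments propagates to its initial condition only.
- Optimizer tolerances default to 1e−12 (noiseless exactness); the recovery
  experiment relaxes ftol/xtol to 1e−8 when noise is present, since the
  objective cannot improve below the noise floor.
- Flat photobleach baselines yield an identity correction; a trending
  baseline that cannot be fitted raises with diagnostics.
- Ties in the fluorescence ordering within a relative tolerance (default
  1e−3) are classified "ambiguous" rather than forced into a class.
- Problem sizes used by the shipped studies: 5-voltage families at 2 kHz
  (2801 samples per sweep), 50 replicates for the ordering-recovery study,
  20 randomized model/protocol pairs for the oracle comparison. These are
  the package's standard study sizes; all are parameters.

## Known limitations

- The sequential three-state scheme is the minimal adequate description;
  dimeric/cooperative multi-state schemes are out of scope.
- Gating-current prediction and pH-dependent gating are not modelled.
- The fitter assumes bleach-corrected inputs; it does not co-estimate
  bleaching.
- Recovery guarantees are empirical (simulation-based), not analytic
  identifiability proofs.
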