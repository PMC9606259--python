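# vcfkit

Voltage-clamp fluorometry (VCF) analysis built around a sequential
three-state model of voltage-sensor gating, for the Hv1 proton channel and
similar voltage-sensing domains labeled with an environment-sensitive dye.

VCF reports conformational change as a small fluorescence deflection,
ΔF/F_h of a few percent, whose shape encodes how the dye's environment
changes as the sensor moves: quenching residues near the dye and the dye's
transit between lipid and aqueous phases. `vcfkit` is for experimentalists
and modellers who want to (a) extract the standard trace metrics from
sweep families, (b) fit a mechanistic gating model across voltages and
constructs, and (c) validate the whole analysis on realistic synthetic
data.

## The model

Gating is a sequential Markov scheme `1 ⇄ 2 ⇄ 3` (resting, intermediate,
activated). State *i* has free energy g_i (kT, g₁ = 0) and gating charge
q_i (e₀, q₁ = 0); transitions pass through barrier states ij, giving
voltage-dependent rates

    r_ij(V) = exp(−(Δg_ij + Δq_ij·V/kT_volts)) / τ ,   Δx_ij = x_ij − x_i.

The observed fluorescence is F(t) = Σᵢ Pᵢ(t)·Fᵢ with per-state intensities
F₁, F₂, F₃. Their ordering defines the construct classes: F₃ > F₁ > F₂
(no quencher; biphasic with repolarisation "hook"), F₁ > F₃ > F₂ (weak
quencher), F₁ > F₂ > F₃ (strong quencher; monotonic). The fitting engine
`ThreeStateTraceFitter` (scikit-learn style) recovers state energies,
charges and F-values from multi-voltage ΔF/F_h trace families by global
nonlinear least squares.

See `docs/methods.md` for conventions, numerical choices and limitations.

## Worked example

Simulate a weak-quencher sweep family, extract metrics, and refit the
model:

```python
import numpy as np
import vcfkit as vk

protocols = vk.make_step_protocol()        # -60 hold, 1-s steps to -60..+100 mV
traces = []
for i, proto in enumerate(protocols):
    scenario = vk.preset_scenario("weak-quencher", proto,
                                  noise_sd=0.001, bleach_fraction=0.0, seed=i)
    trace, truth = vk.generate_trace(scenario)
    traces.append(vk.fittrace_from_vcf(trace, protocol=proto))

m = vk.compute_delta_f(trace, (100.0, 1100.0))   # the +100 mV sweep
print(f"dF_peak/F_h = {m.dF_peak_pct:.2f}%  dF_ss/F_h = {m.dF_ss_pct:.2f}%  "
      f"dF_tail/F_h = {m.dF_tail_pct:.2f}%  dF_hook/F_h = {m.dF_hook_pct:.2f}%")

fitter = vk.ThreeStateTraceFitter(n_starts=8, seed=0).fit(traces)
fp = fitter.fluorescence_["weak-quencher"]
print("fitted F state:", np.round(fp.f_state, 4),
      "->", vk.classify_shape(fp).label)
```

Output:

```
dF_peak/F_h = -4.45%  dF_ss/F_h = -2.07%  dF_tail/F_h = -2.92%  dF_hook/F_h = -0.85%
fitted F state: [1.     0.955  0.9851] -> weak-quencher
```

The +100 mV sweep dips fast (1→2 darkens the dye), partially recovers
during the slow 2→3 step, and undershoots again on repolarisation (the
hook, dF_tail < dF_ss). The fit recovers the generating intensities
(true F₂ = 0.955, F₃ = 0.985) and classifies the construct correctly.

The binomial heterodimer calculator answers the labeling-composition
question directly from the mixing fraction:

```
$ vcfkit heterodimer --labeled-fraction 0.2
...
singly-labeled share of signal-competent dimers: 88.9%
```

A full pipeline is available from the shell: `vcfkit simulate`,
`vcfkit metrics`, `vcfkit fit`, `vcfkit recover` (see `vcfkit --help`),
all driven by a YAML/JSON config and a single global seed.

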