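# kcmodel

Compartmental modelling and recording analysis for *Drosophila* mushroom-body
Kenyon cells expressing the bacterial sodium channel NaChBac.

Ectopic NaChBac expression is a standard tool for chronically *increasing*
neuronal excitability, yet in Kenyon cells it does the opposite: the channel's
low activation threshold and very slow inactivation produce long plateau
depolarizations ("NaChBac potentials") that drive the endogenous transient
sodium channel (Para) into depolarization block, suppressing normal spiking.
`kcmodel` packages the computational toolchain needed to study this:

- a **multi-compartment Hodgkin–Huxley cable model** of a γ Kenyon cell
  (labelled SWC morphologies with soma/axon/dendrite/tether/pre-SIZ/SIZ
  regions, λ-rule discretization, patch-electrode section, implicit
  branched-tree solver with current- and voltage-clamp sources),
- the **channel formalism** `I = ḡ·m^p·h·(V−E)` with Boltzmann steady states
  and voltage-sigmoid time constants, including the full published NaChBac
  parameterization (activation V½ = −47.21 mV, k = 8.17 mV, p = 3;
  inactivation V½ = −56.68 mV, k = 6.08 mV) and per-region conductance
  presets for wild-type and NaChBac-expressing model cells,
- the **model-level experiments**: passive-property fitting to
  hyperpolarizing current families (statsmodels-style `PassiveFit.fit()` →
  results object with `summary()`), F–I curves and rheobase, and a uniform
  NaChBac conductance sweep,
- the **patch-clamp analysis procedures**: input resistance/capacitance,
  spike waveform features (onset by peak second derivative, height, peak
  dV/dt), NaChBac current and plateau-potential metrics, decay-constant
  fitting, biphasic fast-inward-event detection, and the steady-state
  decomposition `I_obs = I_leak + I_Nr + I_K`,
- the **calcium-imaging statistics**: ΔF/F traces, per-pixel activity maps
  with frame rejection, population sparseness
  `SP = (1/(1−1/N))·(1 − (Σrᵢ/N)²/(Σrᵢ²/N))` and inter-odour correlations,
- **synthetic-data generators** with ground-truth sidecars (γ-KC-like
  morphologies, clamp sweep sets, activity maps), so the entire pipeline is
  testable without any external download.

The package targets electrophysiologists and modellers who want to reproduce
or extend the analysis on their own recordings or on the bundled synthetic
surrogate cell.

## Worked example

```python
import kcmodel as kc

# build the wild-type surrogate model with the published conductances
morph = kc.default_morphology(seed=0)
model = kc.CompartmentalModel.from_morphology(
    morph, kc.PassiveParams(), kc.presets()["WT*"],
    electrode=kc.ElectrodeSpec())

# the printed electrode cylinder and its lumped equivalents
print(kc.electrode_properties(kc.ElectrodeSpec()))
# {'axial_resistance_mohm': 13.083363927857874,
#  'seal_resistance_gohm': 8.001756817088754,
#  'capacitance_pf': 2.0106192982974678}

# F-I curve over the experimental current family (1 s steps, 10 pA grid)
fic = kc.fi_curve(model, kc.current_step_protocol(V0=-60.0))
print(fic.rheobase_pa)        # 20.0  (pA; smallest step with >= 1 spike)
print(fic.counts[-1])         # 177   (spikes at +100 pA)
```

The electrode values are the cylinder's closed-form lumped equivalents
(≈13 MΩ axial resistance to the midpoint, ≈8 GΩ seal, ≈2 pF). The rheobase
of 20 pA means the wild-type model cell first fires within the 1 s step at
the 20 pA grid point, and it fires repetitively (177 spikes) at +100 pA.

Switching the conductance preset to `"NaChBac*"` and stepping 20 pA from
−69 mV produces a >900 ms plateau depolarization during which the
transient-Na inactivation gate at the spike initiation zone collapses to
≈0.03 and fast spiking stops — the depolarization-block mechanism.

A command-line interface exposes the same operations
(`kcmodel simulate | fit-passive | fi-curve | nachbac-sweep |
analyze-ephys | analyze-imaging | synth`); every run serializes its
configuration and seed into the output directory.

## Limitations

The bundled morphology is a scaled-down synthetic surrogate, not the
electron-microscopy reconstruction used for full-scale modelling, and the
endogenous NaT/NaP/K kinetics are a clearly-labelled synthetic stand-in file
(`src/kcmodel/data/endogenous_channels_synthetic.yaml`); quantities that
depend on total membrane area or on the exact endogenous kinetics (e.g. the
NaChBac sweep's crossing density) therefore differ from full-scale values.
See `docs/methods.md` for the model equations, numerical scheme, parameter
provenance and the design decisions behind each analysis procedure.
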