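# Methods

## The model

A Kenyon cell is represented as a branched cable of iso-potential
compartments. Each SWC edge is a section; every section is subdivided so no
segment exceeds 0.1 λ, with the length constant

    λ = sqrt(d · R_m / (4 · R_a)),   R_m = 1/g_leak,

evaluated at the section's midpoint diameter. Each inter-node edge is a
truncated cone: membrane area π(r₁+r₂)L and axial resistance R_a·L/(π r₁ r₂);
with linearly interpolated radii the total frustum area is conserved exactly
under subdivision. A lone label-1 root node is read as a spherical soma and
mapped to the equivalent cylinder L = d = 2r (same 4πr² area). Region labels
follow the mushroom-body scheme soma = 1, axon = 2, dendrites = 3,
tether = 11, pre-SIZ = 12, SIZ = 13; unknown labels are preserved and
flagged.

Every compartment carries a leak (g_leak, E_rev) and Hodgkin–Huxley channels

    I = ḡ · m^p · h · (V − E)        [mS/cm² · mV = µA/cm²]
    dx/dt = (x∞(V) − x)/τ_x(V),      x ∈ {m, h}

with Boltzmann steady states and voltage-sigmoid time constants
τ(V) = base + amp/(1 + exp((V − mid)/slope)). Activation curves are
evaluated as 1/(1+exp((V½−V)/|k|)) and inactivation as
1/(1+exp((V−V½)/|k|)): the physiologically monotone convention (activation
rises, inactivation falls with depolarization) for the published
half-voltages and slope magnitudes. Midpoint values are unaffected by this
choice.

### Channel parameters

NaChBac (`data/nachbac.yaml`) is fully parameterized from published
whole-cell HEK293 kinetics: p = 3, E = +60 mV, activation V½ = −47.21 mV,
k = 8.17 mV, inactivation V½ = −56.68 mV, k = 6.08 mV, with
τ_m = 125258.35 − 125253.86/(1+exp(−0.06(V+187.78))) ms (≈6 ms depolarized,
≈10⁵ ms far hyperpolarized — taken at face value from the published fit)
and τ_h = 165.14 + 36.12/(1+exp((V+24.60)/5.158)) ms. These kinetics are
what make the channel interesting: it activates slowly at low thresholds
and inactivates over ~180 ms, producing plateau potentials.

The endogenous transient Na (NaT), persistent Na (NaP) and
delayed-rectifier K channels come from a cited model whose kinetic
parameters are not printed anywhere we can bundle; the file
`data/endogenous_channels_synthetic.yaml` is a clearly-labelled synthetic
stand-in in the same formalism, calibrated **once** so that the published
per-region conductance presets (`data/conductance_presets.yaml`, six rows:
three wild-type, three NaChBac-expressing, starred rows the representative
models) produce Kenyon-cell-like behaviour on the bundled surrogate
morphology: small somatic spikes initiated at the SIZ, rheobase on the
10 pA protocol grid, repetitive firing at +100 pA, and depolarization
block under the NaChBac* preset. Edit that file to substitute the
published set. Reversal potentials: Na-family +60 mV, K −80 mV.

Region semantics of the presets: an explicit soma/SIZ entry **overrides**
the whole-cell "all" baseline (not additive). This is an assumption — the
published table does not state it — chosen to match the description of low
NaChBac density throughout the cell with higher density in soma and SIZ.

### Electrode

The patch electrode is a passive cylinder attached to the soma
(10 µm × 1 µm, R_a = 205.513 Ω·cm, g_leak = 3.978e−4 S/cm²,
C_m = 6.4 µF/cm²), represented by one midpoint compartment coupled through
the electrode's half axial resistance in series with the soma segment's
half resistance. Its closed-form lumped values are ≈13.08 MΩ (axial, to
midpoint), ≈8.00 GΩ (seal) and ≈2.01 pF. Current is injected at the soma by
default — the electrode contributes only its RC load — with
`inject_at="electrode"` available, since the original description
("electrode placement and recording section were the same") does not
disambiguate the two.

### Numerics

The voltage update is implicit with the branched linear system solved
exactly each step by Hines elimination (parent index < child index; cost
linear in compartment count). The default scheme is Crank–Nicolson with
gates advanced by the exact exponential update at the current voltage —
the usual staggered second-order method; backward Euler is available via
`order=1`. The clamp source term stays fully implicit in both schemes.
Default dt = 0.025 ms. Implicit stability matters because NaChBac gating is
stiff (τ_m spans 6–10⁵ ms). Under Crank–Nicolson, spike counts are
invariant to dt halving (0.025 → 0.0125 ms) and to spatial refinement
(0.1 λ → 0.05 λ); backward Euler shifts counts by ~1 per 50 at these steps,
which is why it is not the default. Voltage clamp is an ideal source
implemented as a 10⁶ µS series conductance (error ~nA/10⁶ µS ≈ 10⁻⁹ mV);
a finite series resistance is optional. Gate updates are exact
exponentials, so under a fixed clamp voltage the simulated gates equal the
analytic solution and single-compartment clamp currents agree with a
stiff-ODE (LSODA) oracle to ≲10⁻⁶ %.

Degenerate inputs: zero-length or zero-diameter sections, non-positive
radii, cycles, orphan nodes and multiple roots are rejected at morphology
validation; NaN initial voltages are rejected; non-finite simulated traces
raise a simulation error naming the offending step.

## Model-level experiments

**Spike detection.** Local maxima with prominence above 1 mV, where
prominence is evaluated in a ±10 ms window around each peak. The local
window is the "relative threshold": it excludes the broad early NaChBac
surge and the relaxation peak at the end of a sustained subthreshold step,
both of which have large global but negligible local prominence. Firing
frequency is spikes during the 1 s step divided by the step duration;
rheobase is searched on the protocol's 10 pA grid only.

**Passive fitting.** `PassiveFit` estimates C_m, g_leak, R_a from
hyperpolarizing families by bound-constrained least squares
(R_a ∈ [30, 400] Ω·cm, C_m ∈ [0.6, 2.6] µF/cm², the published plausibility
ranges), fitting all sweeps simultaneously after subtracting each sweep's
mean over its first 200 ms. For a linear passive membrane that subtraction
removes all information about E_rev, so E_rev is estimated separately from
the raw pre-step baseline (the resting potential at zero holding current).
The optimizer works on (C_m, log₁₀ g_leak, R_a); the segmentation is fixed
once (reference passive values) so the objective is smooth in the
parameters; the simulation step inside the objective defaults to the
acquisition step (0.025 ms) because R_a is weakly identified from a somatic
recording and a coarser step's small systematic shape error biases it by
~15%. Noise-free self-recovery is exact; at 0.5 mV added noise the
four-step (−40…−10 pA) family recovers all three parameters within 10%
(R_a is the limiting one). Non-convergence is flagged on the result, not
raised.

**NaChBac conductance sweep.** A uniform NaChBac density is applied over
the entire morphology per grid point and the total spike count across the
current family is compared with the zero-NaChBac model. On the surrogate
the characteristic bimodal profile appears — totals rise above baseline at
low densities (extra inward drive) and fall below it once the
NaChBac-mediated depolarization inactivates NaT — with the crossing near
2–4 mS/cm² depending on the current family used. The full-scale
reconstruction crosses near 0.175 mS/cm²; the difference reflects the
surrogate's much smaller dendritic load and the stand-in NaT kinetics, and
the package reports the crossing as computed.

## Patch-clamp analysis

All procedures operate on a `SweepSet` (uniform time grid, one row per
step, onset/offset metadata; nominal 50 kHz sampling, 1 kHz low-pass).
Smoothing windows are given in ms and converted to odd sample counts, so
results are sampling-rate independent.

- **Passive properties**: exponential fit to the hyperpolarization of the
  most negative step; R = plateau ΔV/I, C = τ/R; cells under 0.8 GΩ are
  flagged as QC-excluded.
- **Spike features**: ±20 ms waveform snippets (edge spikes skipped with a
  warning); onset = peak second derivative within 5 ms before the peak,
  with 2 ms moving-average smoothing at each differentiation step and a
  small absolute floor (0.01 mV/ms²) so featureless ramps return "no
  onset"; height = peak − onset voltage; upstroke speed = peak dV/dt in
  the same window after 0.6 ms smoothing; per-cell minimum onset voltage.
- **NaChBac current**: 50 ms moving-median smoothing (rejects fast
  unclamped-spike currents), steady state = median of the last 100 ms of
  the step, peak inward within the first 100 ms, density = peak/C.
- **NaChBac potential**: per depolarizing step, subtract the plateau
  (lowest 200 ms mean within the step) and average the normalized voltage
  from its first positive crossing to the step end; the step maximizing
  the metric is the cell's value ("biggest" is defined self-consistently
  by the metric itself). The metric is invariant to constant offsets.
- **Decay τ**: the step with the biggest inward density (cells under
  2 pA/pF excluded), normalized to its peak and fitted with −a·exp(−t/τ).
  The published normalized form pins a = 1; the free amplitude is the
  default because the median filter attenuates the measured peak and
  pinning the amplitude to it leaks that attenuation into τ (the forms
  coincide when normalization is exact). The first half-median-window
  after the peak, where the centered filter mixes rise and pre-step
  samples, is excluded from the fit.
- **Fast inward events**: final 400 ms of each trace, moving-average
  smoothing (default 1.4 ms; the useful range is 0.8–2.2 ms per cell); an
  event needs a dI/dt trough < −2.5 pA/ms followed by a peak > +2.5 pA/ms
  within 3 ms (each |prominence| > 5 pA/ms) and a current trough of
  prominence > 2 pA between them; waveforms are averaged −3…+6 ms around
  the current trough, unsmoothed. Detected counts are monotone
  non-increasing in every threshold. Note that prominence of a detector
  peak adjacent to the analysis-window boundary is clipped by the window,
  exactly as in the original findpeaks-based procedure.
- **Steady-state decomposition**: steady-state current = median of the
  last 100 ms minus the pre-step baseline; cells whose pre/post baselines
  differ by > 15 pA anywhere are flagged; leak from a linear fit over
  −100…−70 mV; the residual NaChBac current I_Nr is measured at the
  −60…−40 mV step with the biggest observed peak NaChBac current (where
  I_K = 0) as I_obs − I_leak, scaled to other steps by the ratio
  I_Nr/I_Np,obs using only inward I_Np,obs; I_K = I_obs − I_leak − I_Nr
  holds exactly per step by construction. With no inward NaChBac current
  anywhere, I_Nr = 0 with a flag.

## Imaging statistics

ΔF/F traces are background-subtracted, baselined on the pre-stimulus mean
and smoothed with a 0.2 s boxcar; traces at different frame rates are
linearly interpolated to a common rate before averaging. Activity maps
Gaussian-smooth each frame (5×5 kernel, σ = 2 px, reflect edges), discard
frames whose correlation with the baseline image falls below a
user-chosen threshold (axial-movement rejection; the threshold is
preparation-specific, mirroring the per-brain manual choice), and compute
per-pixel ΔF/F with no thresholding of low-responding pixels. Population
sparseness uses the Vinje–Gallant/Willmore–Tolhurst statistic; negative
pixels enter as-is, so the [0,1] bound is only guaranteed for non-negative
maps and negative-dominated maps are flagged. Inter-odour correlations
align maps by the integer translation (±10 px) maximizing baseline
correlation, mask pixels below a required baseline-fluorescence threshold
(no default is pretended — the original value is never stated), and take
Pearson correlations of the masked vectors.

## Synthetic data

The generators define the testing conditions and carry ground-truth
sidecars (seed, parameters, generator version; bit-identical
regeneration).

- **Morphology**: single-soma tree soma–tether–{dendritic claws,
  pre-SIZ–SIZ–axon}, all six labels present, claw directions randomized
  (electrically irrelevant — section lengths and radii are fixed).
  Defaults: soma r = 3 µm, tether 30×0.5 µm, 5 claws of 20×0.4 µm,
  pre-SIZ 20×0.4 µm, SIZ 25×0.6 µm, axon 40×0.4 µm — total area
  ≈ 500 µm², input resistance ≈ 1.8 GΩ at g_leak = 1.1e−4 S/cm²,
  Kenyon-cell-like. The SIZ sits just distal to the dendrite/pre-SIZ
  junction on the soma-to-axon path. Whether the tether ends at the
  dendrite root or at the pre-SIZ junction is configurable
  (`tether_target`), since the labelling scheme does not fix it. The
  geometry was calibrated once, together with the stand-in channel file,
  to reproduce the qualitative wild-type/NaChBac regimes; it is a
  scaled-down surrogate, roughly an order of magnitude smaller in
  membrane area than the real reconstruction.
- **Clamp recordings**: fast mode synthesizes closed-form templates (RC
  step responses, difference-of-exponential spikes, a slow inward current
  with linear 20 ms rise and exact single-exponential decay — so the decay
  constant is recoverable without shape bias — a Boltzmann-gated steady
  outward current, and sharp biphasic fast events), resampled at 50 kHz
  with optional Gaussian noise low-pass filtered at 1 kHz. Simulate mode
  runs the compartmental model and resamples its output. Fast mode is what
  keeps the analysis tests at seconds.
- **Activity maps**: log-normal pixel responses r = exp(σz) with the
  latent z mixing a shared and an odour-specific standard normal with
  weight w. σ is calibrated per map on the realized sample (Brent root
  find), so the empirical sparseness hits the target to ~10⁻³ rather than
  only in expectation; the implied pairwise correlation is the log-normal
  value (e^{wσ²}−1)/(e^{σ²}−1), stored in the ground truth.

What passing tests on synthetic data do **not** show: performance on real
recordings with drift, series-resistance artefacts, seal instabilities or
biological spike-shape variability, nor full-scale quantitative values
that depend on the true morphology and endogenous kinetics (rheobase
happens to land at the realistic 20 pA on the surrogate; the NaChBac
crossing density does not transfer).

## Known limitations

- The endogenous channel file is a synthetic stand-in, not the cited
  published parameter set.
- The surrogate morphology is desk-scale; full-scale reproduction needs
  the external EM-reconstructed skeleton, which this package reads but
  does not bundle.
- The imaging module consumes in-memory arrays (and TIFF via `tifffile`
  in the CLI); motion correction is out of scope.
- PCA across cell-level features and behavioural scoring are out of
  scope.
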