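# SYNTHETIC stand-in parameters for the endogenous Kenyon-cell channels:
# transient sodium (NaT, Para-like), persistent sodium (NaP) and
# delayed-rectifier potassium (K).  The published model these channels
# are based on does not print its kinetic parameters, so the values here
# are constructed in the same Hodgkin-Huxley formalism (Boltzmann steady
# states, sigmoid time constants) and calibrated once so that the
# wild-type conductance presets produce Kenyon-cell-like firing: small
# somatic spikes initiated at the SIZ, rheobase on the 10 pA protocol
# grid, repetitive firing at +100 pA.  Edit this file to substitute the
# published parameter set.
# tau(V) = base + amp/(1 + exp((V - mid)/slope)), ms.
channels:
  NaT:
    p: 3
    E: 60.0
    activation:
      V12: -40.0
      k: 5.0
      tau: {base: 0.04, amp: 0.26, mid: -45.0, slope: 6.0}
    inactivation:
      V12: -48.0
      k: 3.0
      tau: {base: 1.0, amp: 5.0, mid: -48.0, slope: 5.0}
  NaP:
    p: 1
    E: 60.0
    activation:
      V12: -45.0
      k: 5.0
      tau: {base: 1.0, amp: 3.0, mid: -50.0, slope: 6.0}
  K:
    p: 4
    E: -80.0
    activation:
      V12: -37.0
      k: 8.0
      tau: {base: 2.0, amp: 5.0, mid: -45.0, slope: 8.0}
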