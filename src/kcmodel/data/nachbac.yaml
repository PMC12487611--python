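# NaChBac: prokaryotic voltage-gated sodium channel (Bacillus halodurans).
# Gating parameterized from published whole-cell HEK293 recordings.
# Steady states: Boltzmann with V12 (mV) and slope magnitude k (mV);
# time constants: tau(V) = base + amp/(1 + exp((V - mid)/slope)), ms.
# The activation time constant's large base/amp coefficients are taken at
# face value from the published fit (tau_m ~ 6 ms at 0 mV, ~10^2 ms near rest).
channels:
  NaChBac:
    p: 3
    E: 60.0
    activation:
      V12: -47.21
      k: 8.17
      tau: {base: 125258.35, amp: -125253.86, mid: -187.78, slope: -16.666666666666668}
    inactivation:
      V12: -56.68
      k: 6.08
      tau: {base: 165.14, amp: 36.12, mid: -24.60, slope: 5.158}
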