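# Compartment-specific maximal conductances (mS/cm^2) for the six
# published model parameter sets: three wild-type (WT) and three
# NaChBac-expressing rows.  Starred rows (WT*, NaChBac*) are the
# representative models.  Region keys are SWC labels
# (1 = soma, 2 = axon, 13 = SIZ); "all" is a whole-cell baseline that
# explicit region entries override (not add to).
presets:
  WT-high:
    NaT: {13: 88.0, 2: 66.0}
    NaP: {13: 0.414}
    K: {13: 800.0, 2: 60.0}
  "WT*":
    NaT: {13: 40.0, 2: 30.0}
    NaP: {13: 0.18}
    K: {13: 200.0, 2: 15.0}
  WT-mid:
    NaT: {13: 80.0, 2: 60.0}
    NaP: {13: 0.36}
    K: {13: 530.0, 2: 39.75}
  "NaChBac*":
    NaT: {13: 25.0, 2: 18.75}
    NaP: {13: 0.18}
    K: {13: 200.0, 2: 15.0}
    NaChBac: {1: 15.0, 13: 0.3125, all: 0.05}
  NaChBac-low:
    NaT: {13: 5.714, 2: 4.286}
    NaP: {13: 0.018}
    K: {13: 400.0, 2: 30.0}
    NaChBac: {1: 0.55, 13: 0.00833, all: 0.00833}
  NaChBac-mid:
    NaT: {13: 8.0, 2: 6.0}
    NaP: {13: 0.09}
    K: {13: 500.0, 2: 37.5}
    NaChBac: {1: 2.0, 13: 0.15, all: 0.05}
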