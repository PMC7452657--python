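# Three-class synthetic benchmark: per-class feature means and SDs in the
# canonical feature order
#   capacitance (pF), input_resistance (MOhm), rmp (mV), sag (mV),
#   rheobase (pA), ap_amplitude (mV), ahp_amplitude (mV), ap_half_width (ms),
#   max_rise_rate (mV/ms), max_fall_rate (mV/ms), freq_adaptation, amp_adaptation.
# Values are plausible whole-cell phenotypes; every class pair differs by
# >= 3 pooled SDs on >= 3 features.
MSN:
  means: [90.0, 120.0, -85.0, 1.0, 150.0, 75.0, 12.0, 1.2, 250.0, 90.0, 1.5, 0.95]
  sds:   [15.0,  30.0,   4.0, 0.8,  30.0,  8.0,  3.0, 0.2,  40.0, 15.0, 0.4, 0.05]
THIN:
  means: [45.0, 400.0, -60.0, 4.0,  30.0, 65.0, 18.0, 1.0, 180.0, 70.0, 2.0, 0.90]
  sds:   [10.0,  80.0,   5.0, 1.5,  15.0,  8.0,  4.0, 0.2,  40.0, 15.0, 0.5, 0.06]
FAN:
  means: [65.0, 250.0, -70.0, 2.0,  60.0, 70.0, 10.0, 1.8, 150.0, 50.0, 5.0, 0.65]
  sds:   [12.0,  60.0,   4.0, 1.0,  20.0,  8.0,  3.0, 0.25, 35.0, 12.0, 1.2, 0.06]
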