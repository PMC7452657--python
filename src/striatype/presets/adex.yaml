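# Illustrative AdEx phenotypes for the three striatal classes.
# Qualitative only: hyperpolarized/high-rheobase projection-neuron-like cell,
# depolarized/low-rheobase interneuron-like cell, strongly adapting cell.
# Units: C pF, conductances nS, voltages mV, tau_w ms, b pA.
msn:
  C: 120.0
  g_L: 4.0        # Rin 250 MOhm
  E_L: -85.0
  V_T: -50.0
  Delta_T: 1.5
  a: 1.0
  tau_w: 150.0
  b: 40.0
  V_reset: -65.0
  V_cut: 20.0
thin:
  C: 40.0
  g_L: 2.5        # Rin 400 MOhm
  E_L: -65.0
  V_T: -52.0
  Delta_T: 2.0
  a: 0.5
  tau_w: 80.0
  b: 15.0
  V_reset: -62.0
  V_cut: 20.0
fan:
  C: 70.0
  g_L: 3.0        # Rin 333 MOhm
  E_L: -72.0
  V_T: -50.0
  Delta_T: 2.0
  a: 2.0
  tau_w: 3000.0  # slower than the 1 s pulse: adaptation never equilibrates in-sweep
  b: 14.0
  V_reset: -58.0
  V_cut: 20.0
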