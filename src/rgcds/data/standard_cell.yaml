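# Standard regional biophysical parameter set for the ganglion-cell model.
# Channel densities in mS/cm^2 per region; leak reversal in volts;
# Rm in Ohm*cm^2; Ri in Ohm*cm.
densities_mS_cm2:
  Na:
    distal: 20.0
    dendrite: 20.0
    proximal: 20.0
    soma: 5.0
  Kdr:
    distal: 5.0
    dendrite: 5.0
    proximal: 5.0
    soma: 2.0
  HCN:
    distal: 0.005
    dendrite: 0.001
    proximal: 0.0005
    soma: 0.0
passive:
  v_rev_leak_V: -0.068
  rm_ohm_cm2: 28000.0
  ri_ohm_cm: 200.0
  cm_uF_cm2: 1.0
reversal_mV:
  Na: 50.0
  K: -77.0
  HCN: -30.0
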