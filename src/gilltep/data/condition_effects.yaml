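# Approximate published TEP shifts (mV) relative to the -22.3 mV control in
# acclimation (INPA) water, per exposure series.  Positive = depolarization.
isotonic_nacl:
  NaCl_140mM: 22.3
rivers:
  rio_negro_pH4.0: -8.0
  rio_solimoes_pH6.7: 6.0
inpa_ph4:
  pH4.0_HNO3: 14.4
rio_negro_ph7:
  rio_negro_pH7.0: -13.3
hypercapnia:
  CO2_1.5pct: 11.5
  CO2_3pct: 18.5
hypoxia:
  O2_50pct: 14.0
  O2_10pct: 21.0
hyperoxia:
  O2_200pct: -5.0
nacl:
  NaCl_250uM: 6.5
  NaCl_2500uM: 13.5
nh4cl:
  NH4Cl_250uM: 9.5
  NH4Cl_2500uM: 16.5
temperature:
  "21C": -15.5
  "33C": 12.5
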