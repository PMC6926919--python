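# Default assessment configuration.
# Equilibrium factors by building class (degree of radon gas / progeny
# disequilibrium): 0.6 for dwellings and outdoor air, 0.4 for schools and
# other public buildings.  Outdoor radon gas concentration is the UNSCEAR
# worldwide average 10 Bq/m3.
f_eq:
  home: 0.6
  school: 0.4
  public: 0.4
  outdoors: 0.6
outdoor_radon: 10.0
wlm_h_bqm3: 6.37e5   # h Bq/m3 of EEC per working level month
days_per_year: 365
risk:
  beta: 0.0634           # excess relative risk per WLM
  theta_15_24: 0.78      # weight on exposure 15-24 y before attained age
  theta_25plus: 0.51     # weight on exposure >= 25 y before attained age
  lag: 5                 # most recent years excluded from all windows
  phi_breaks: [55, 65, 75]
  phi_values: [1.00, 0.57, 0.29, 0.09]   # attained-age effect modifier
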