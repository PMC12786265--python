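# Reference constants of the nine-state actomyosin crossbridge cycle used by
# spatially explicit sarcomere Monte Carlo simulations.  Shipped for reference
# only: this package does NOT simulate the kinetic cycle; its stochastic
# surrogate (fiberdiff.strain.simulate_crossbridges) replaces it.
binding:
  delta_G_kBT: -4.8          # binding free energy
  equilibrium_constant: 125
  k_forward_per_s: 200       # at zero crossbridge strain
power_stroke_1:
  delta_G_kBT: -3.9
  stroke_nm: 5.5
  k_forward_per_s: 7500
power_stroke_2:
  delta_G_kBT: -6.2
  stroke_nm: 3.5
  k_forward_per_s: 150000.0
phosphate_release:
  equilibrium_constant: 10
  k_plus_after_stroke1_per_s: 80
  k_plus_after_stroke2_per_s: 400
adp_release_detachment:
  k_ADP0_per_s: 100
  second_stroke_delta_nm: 1.0
crossbridge:
  stiffness_pN_per_nm: 1.3
  kBT_pN_nm: 3.91            # at 10 C (283.15 K)
filament_moduli:
  actin_Ka_pN: 65000.0
  myosin_Km_pN: 132000.0
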