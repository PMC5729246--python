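# Estimated transfer-function and resource-usage parameters for the lux/tet/lac
# cascade device collection, by fitting strategy.
#
# Columns:
#   NBM_training    : Hill-only model, sequential fit on the training set
#   BM_training     : burden model, sequential fit on the training set
#   BM_simultaneous : burden model, simultaneous fit on all circuits
#   NBM_weak_tet    : Hill-only fit of the weak-RBS tet NOT gate (T_w)
#
# Units: delta/alpha in AU_R cell^-1 min^-1; K in nM for input blocks (HSL input)
# and AU_R cell^-1 for NOT gates (repressor-level input); eta dimensionless;
# J in AU_R^-1 cell min; Sigma dimensionless; S_m in AU_G cell^-1 min^-1.
constants:
  gamma_tet: 0.0173   # min^-1, LVA-tagged TetR degradation
  gamma_lac: 0.0533   # min^-1, LVA-tagged LacI degradation
  a: 0.0167           # min^-1, RFP maturation
  a_G: 0.0462         # min^-1, GFP maturation

columns:
  NBM_training:
    hill:
      X_1:   {delta: 0.14, alpha: 14.63, K: 4.16,  eta: 1.42, orientation: inducible}
      X_2:   {delta: 0.14, alpha: 9.06,  K: 15.06, eta: 1.24, orientation: inducible}
      X_3:   {delta: 0.16, alpha: 15.81, K: 4.37,  eta: 1.45, orientation: inducible}
      X_rep: {delta: 0.13, alpha: 2.85,  K: 6.67,  eta: 1.32, orientation: repressible}
      T:     {delta: 0.03, alpha: 3.1,   K: 6.47,  eta: 1.59, orientation: repressible}
      L:     {delta: 0.11, alpha: 0.63,  K: 56.39, eta: 1.91, orientation: repressible}
  BM_training:
    hill:
      X_1:   {delta: 0.16, alpha: 36.17, K: 5.39,  eta: 1.51, orientation: inducible}
      X_2:   {delta: 0.26, alpha: 26.76, K: 17.26, eta: 1.25, orientation: inducible}
      X_3:   {delta: 0.18, alpha: 36.9,  K: 7.64,  eta: 1.41, orientation: inducible}
      X_rep: {delta: 0.22, alpha: 4.6,   K: 5.26,  eta: 1.21, orientation: repressible}
      T:     {delta: 0.22, alpha: 3.45,  K: 15.6,  eta: 8.28, orientation: repressible}
      L:     {delta: 0.22, alpha: 0.56,  K: 52.13, eta: 1.93, orientation: repressible}
    burden:
      Sigma: {lambda: 0.2, lac: 1.0, tet: 0.07}
      J_RFP: 0.04
      J_tet: 0.07
      J_lac: 0.01
      S_m: 1.75
  BM_simultaneous:
    hill:
      X_1:   {delta: 0.2,  alpha: 24.33, K: 6.71,  eta: 1.19, orientation: inducible}
      X_2:   {delta: 0.18, alpha: 20.36, K: 31.39, eta: 0.97, orientation: inducible}
      X_3:   {delta: 0.19, alpha: 35.67, K: 8.9,   eta: 1.34, orientation: inducible}
      X_rep: {delta: 0.09, alpha: 8.22,  K: 1.86,  eta: 0.86, orientation: repressible}
      T:     {delta: 0.21, alpha: 4.56,  K: 6.92,  eta: 2.57, orientation: repressible}
      L:     {delta: 0.22, alpha: 0.76,  K: 34.92, eta: 1.93, orientation: repressible}
    burden:
      Sigma: {lambda: 0.36, lac: 0.56, tet: 0.12}
      J_RFP: 0.04
      J_tet: 0.31
      J_lac: 0.01
      S_m: 1.75
  NBM_weak_tet:
    hill:
      Tw:    {delta: 0.02, alpha: 3.03,  K: 63.14, eta: 0.99, orientation: repressible}
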