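# Registry of the cascade circuit collection.
#
# Every circuit is an HSL input block (X_1/X_2/X_3 inducible via P_lux, X_rep
# repressible via P_luxRep), zero to two repressor NOT gates (T = tetR/P_LtetO1,
# L = lacI/P_LlacO1, Tw = weak-RBS tetR variant), and an RFP reporter.  Each
# base circuit exists with ("rg") and without ("r") the constitutive GFP
# monitor cassette; ids carry the suffix.
#
# sigma_class assigns the input block's constitutive LuxR cassette to one of the
# three lumped burden terms (by the promoter driving luxR: lambda = P_R,
# lac = P_LlacO1, tet = P_LtetO1).  The per-block promoter assignment is
# configuration, not model structure; edit here to explore alternatives.
input_blocks:
  X_1:   {orientation: inducible,  sigma_class: lambda}
  X_2:   {orientation: inducible,  sigma_class: lac}
  X_3:   {orientation: inducible,  sigma_class: tet}
  X_rep: {orientation: repressible, sigma_class: lambda}

training:
  - {input: X_1,   gates: []}
  - {input: X_2,   gates: []}
  - {input: X_3,   gates: []}
  - {input: X_rep, gates: []}
  - {input: X_2,   gates: [T]}
  - {input: X_3,   gates: [L]}

test:
  - {input: X_1,   gates: [T]}
  - {input: X_1,   gates: [L]}
  - {input: X_rep, gates: [T]}
  - {input: X_rep, gates: [L]}
  - {input: X_1,   gates: [L, T]}
  - {input: X_1,   gates: [T, L]}
  - {input: X_rep, gates: [L, T]}
  - {input: X_rep, gates: [T, L]}

weak_tet:
  - {input: X_2,   gates: [Tw], role: training}
  - {input: X_1,   gates: [Tw, L], role: test}
  - {input: X_rep, gates: [Tw, L], role: test}
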