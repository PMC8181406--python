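# Residue property tables, version 1.
#
# volume            : residue volumes in cubic Angstroms (Zamyatnin 1972).
# hydrophobicity    : Kyte-Doolittle hydropathy index (default scale;
#                     configurable at load time).
# formal_charge     : side-chain formal charge at physiological pH; His is
#                     0.5 by default (partially protonated), configurable.
# helix_propensity  : helix propensity in kcal/mol relative to Ala
#                     (Pace & Scholtz 1998); larger = worse helix former.
# disorder_propensity: TOP-IDP disorder propensity (Campen et al. 2008);
#                     larger = more disorder-promoting.
# max_sasa          : maximum solvent-accessible surface area (A^2) of residue
#                     X in an extended Gly-X-Gly tripeptide (Tien et al. 2013,
#                     theoretical values); denominators for relative SASA.
version: 1
volume:
  A: 88.6
  R: 173.4
  N: 114.1
  D: 111.1
  C: 108.5
  Q: 143.8
  E: 138.4
  G: 60.1
  H: 153.2
  I: 166.7
  L: 166.7
  K: 168.6
  M: 162.9
  F: 189.9
  P: 112.7
  S: 89.0
  T: 116.1
  W: 227.8
  Y: 193.6
  V: 140.0
hydrophobicity:
  A: 1.8
  R: -4.5
  N: -3.5
  D: -3.5
  C: 2.5
  Q: -3.5
  E: -3.5
  G: -0.4
  H: -3.2
  I: 4.5
  L: 3.8
  K: -3.9
  M: 1.9
  F: 2.8
  P: -1.6
  S: -0.8
  T: -0.7
  W: -0.9
  Y: -1.3
  V: 4.2
formal_charge:
  K: 1.0
  R: 1.0
  D: -1.0
  E: -1.0
  H: 0.5
helix_propensity:
  A: 0.0
  L: 0.21
  R: 0.21
  M: 0.24
  K: 0.26
  Q: 0.39
  E: 0.40
  I: 0.41
  W: 0.49
  S: 0.50
  Y: 0.53
  F: 0.54
  H: 0.61
  V: 0.61
  N: 0.65
  T: 0.66
  C: 0.68
  D: 0.69
  G: 1.00
  P: 3.16
disorder_propensity:
  W: -0.884
  F: -0.697
  Y: -0.510
  I: -0.486
  M: -0.397
  L: -0.326
  V: -0.121
  N: 0.007
  C: 0.020
  T: 0.059
  A: 0.060
  G: 0.166
  R: 0.180
  D: 0.192
  H: 0.303
  Q: 0.318
  S: 0.341
  K: 0.586
  E: 0.736
  P: 0.987
max_sasa:
  A: 129.0
  R: 274.0
  N: 195.0
  D: 193.0
  C: 167.0
  Q: 225.0
  E: 223.0
  G: 104.0
  H: 224.0
  I: 197.0
  L: 201.0
  K: 236.0
  M: 224.0
  F: 240.0
  P: 159.0
  S: 155.0
  T: 172.0
  W: 285.0
  Y: 263.0
  V: 174.0
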