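# Bundled modification registry for histone PTM discovery.
#
# Each entry: name; composition (compact formula; negative counts allowed,
# heavy isotopes 2H/13C/15N start a whitespace-separated chunk) OR an
# explicit mass in Da; targets (residue letters and/or N-term / C-term /
# protein-N-term); category (biological | chemical_artifact |
# derivatization); optional neutral_losses (compositions lost from
# fragments carrying the modification); optional
# blocks_lysine_derivatization (defaults true — whether the mark occupies
# the lysine epsilon-amine and so prevents chemical acylation there).
#
# This is a static list, not a Unimod mirror.  Extend by copying this file
# and passing it to Registry.from_yaml, or via Registry.add.
modifications:
  # --- classical marks ------------------------------------------------
  - {name: acetyl, composition: C2H2O, targets: [K, protein-N-term], category: biological}
  - {name: methyl, composition: CH2, targets: [K, R], category: biological,
     blocks_lysine_derivatization: false}
  - {name: dimethyl, composition: C2H4, targets: [K, R], category: biological}
  - {name: trimethyl, composition: C3H6, targets: [K], category: biological}
  - {name: phospho, composition: HPO3, targets: [S, T, Y], category: biological,
     neutral_losses: [H3PO4]}
  # --- short-chain acylations ----------------------------------------
  - {name: formyl, composition: CO, targets: [K], category: biological}
  - {name: lactyl, composition: C3H4O2, targets: [K], category: biological}
  - {name: malonyl, composition: C3H2O3, targets: [K], category: biological,
     neutral_losses: [CO2]}
  - {name: crotonyl, composition: C4H4O, targets: [K], category: biological}
  - {name: butyryl, composition: C4H6O, targets: [K], category: biological}
  - {name: glutaryl, composition: C5H6O3, targets: [K], category: biological}
  - {name: benzoyl, composition: C7H4O, targets: [K], category: biological}
  - {name: hydroxyisobutyryl, composition: C4H6O2, targets: [K], category: biological}
  - {name: glyceroyl, composition: C3H4O3, targets: [K], category: biological}
  - {name: pyruvoyl, composition: C3H2O2, targets: [K], category: biological}
  - {name: ubiquitinyl-GG, composition: C4H6N2O2, targets: [K], category: biological}
  # --- glycation adducts (AGEs) --------------------------------------
  - {name: hexose, composition: C6H10O5, targets: [K], category: biological}
  - {name: carboxymethyl, composition: C2H2O2, targets: [K], category: biological}
  - {name: carboxyethyl, composition: C3H4O2, targets: [K], category: biological}
  - {name: G-H1, composition: C2O, targets: [R], category: biological}
  - {name: MG-H1, composition: C3H2O, targets: [R], category: biological}
  # --- chemical artifacts --------------------------------------------
  - {name: oxidation, composition: O, targets: [M, H, W, K], category: chemical_artifact}
  - {name: quinone, composition: O2H-2, targets: [H, W, Y], category: chemical_artifact}
  # the in-gel +13.9792 Da adduct co-occurs with propionyl on K (their sum,
  # +70.0054, is isobaric with pyruvoyl), so it does not displace it
  - {name: gel-artifact-13.98, mass: 13.9792, targets: [K], category: chemical_artifact,
     blocks_lysine_derivatization: false}
  - {name: propionyl-ST, composition: C3H4O, targets: [S, T], category: chemical_artifact}
  # --- derivatization chemistry --------------------------------------
  - {name: propionyl, composition: C3H4O, targets: [K, N-term], category: derivatization}
  - {name: phenyl-isocyanate, composition: C7H5NO, targets: [N-term], category: derivatization}
  - {name: d3-acetyl, composition: C2 H-1 2H3 O, targets: [K, N-term], category: derivatization}
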