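# Per-strain generator presets: one laboratory strain (BY4743) and four
# industrial Saccharomyces cerevisiae strains.  Values are the measured
# means and SDs of the phenotype panel: cell-wall composition (% of wall
# mass), octane hydrophobicity index (%), surface stiffness (kPa), specific
# adhesion-event frequency (%), mannan-chain contour length (nm), cell
# size (um).  adhesion_probability is the per-curve specific-event rate the
# retract-curve generator plants (fraction, not %).
BY4743:
  chitin_pct: [4.3, 0.8]
  b13_pct: [44.7, 2.9]
  b16_pct: [19.5, 1.3]
  mannan_pct: [33.5, 2.8]
  hydrophobicity_pct: [7.8, 4.2]
  stiffness_kPa: [483.0, 61.0]
  adhesion_pct: [8.0, 1.5]
  contour_nm: [64.8, 30.0]
  size_um: [3.8, 0.7]
  adhesion_probability: 0.10
  polymer_model: FJC
L71:
  chitin_pct: [5.7, 1.1]
  b13_pct: [30.8, 2.2]
  b16_pct: [29.4, 1.7]
  mannan_pct: [32.3, 1.3]
  hydrophobicity_pct: [25.1, 5.3]
  stiffness_kPa: [637.0, 178.0]
  adhesion_pct: [25.0, 6.0]
  contour_nm: [20.0, 14.7]
  size_um: [5.0, 1.2]
  adhesion_probability: 0.25
  polymer_model: FJC
L62:
  chitin_pct: [9.9, 1.1]
  b13_pct: [20.4, 1.9]
  b16_pct: [23.1, 2.7]
  mannan_pct: [46.5, 1.3]
  hydrophobicity_pct: [23.8, 9.7]
  stiffness_kPa: [239.0, 52.0]
  adhesion_pct: [33.0, 4.0]
  contour_nm: [52.6, 13.0]
  size_um: [3.8, 0.9]
  adhesion_probability: 0.33
  polymer_model: FJC
L60:
  chitin_pct: [4.5, 0.7]
  b13_pct: [19.6, 5.4]
  b16_pct: [24.1, 4.7]
  mannan_pct: [46.5, 3.7]
  hydrophobicity_pct: [23.1, 6.8]
  stiffness_kPa: [438.0, 64.0]
  adhesion_pct: [28.0, 4.0]
  contour_nm: [25.1, 4.3]
  size_um: [4.4, 1.0]
  adhesion_probability: 0.28
  polymer_model: FJC
L69:
  chitin_pct: [3.9, 1.0]
  b13_pct: [34.1, 3.6]
  b16_pct: [18.8, 3.1]
  mannan_pct: [43.5, 2.5]
  hydrophobicity_pct: [45.6, 5.7]
  stiffness_kPa: [230.0, 82.0]
  adhesion_pct: [21.0, 2.0]
  contour_nm: [96.9, 8.3]
  size_um: [4.2, 1.1]
  adhesion_probability: 0.21
  polymer_model: WLC
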