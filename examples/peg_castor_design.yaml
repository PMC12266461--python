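# Two-class PEG-castor-oil-like design: free PEG (apex ~m/z 834) plus
# ethoxylated glycerol (apex ~m/z 1392); Type 2 has a 1.5x higher
# glycerol:PEG abundance ratio than Type 1.
classes:
  Type1:
    - {name: PEG, base_mass: 18.0106, abundance: 1.0, mean_eo: 18.0, isotope_lambda: 0.39}
    - {name: glycerol-EO, base_mass: 92.0473, abundance: 0.4, mean_eo: 29.0, isotope_lambda: 0.65}
  Type2:
    - {name: PEG, base_mass: 18.0106, abundance: 1.0, mean_eo: 18.0, isotope_lambda: 0.39}
    - {name: glycerol-EO, base_mass: 92.0473, abundance: 0.6, mean_eo: 29.0, isotope_lambda: 0.65}
noise_sd: 1.0e-4
replicate_cv: 0.10
abundance_cv: 0.10
matrix_peaks: [[552.3, 0.05], [569.2, 0.08]]
mz_range: [500.0, 2200.0]
n_samples_per_class: 10
n_replicates: 4
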