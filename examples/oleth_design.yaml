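# Three-class Oleth-20-like design: ethoxylated oleyl alcohol (main series)
# and ethoxylated cetyl alcohol.  R1's oleyl envelope mean is 2 EO units
# higher; R3 carries a larger cetyl fraction.
classes:
  R1:
    - {name: oleyl-EO, base_mass: 268.2766, abundance: 1.0, mean_eo: 22.0, isotope_lambda: 0.41}
    - {name: cetyl-EO, base_mass: 242.2610, abundance: 0.12, mean_eo: 20.0, isotope_lambda: 0.39}
  R2:
    - {name: oleyl-EO, base_mass: 268.2766, abundance: 1.0, mean_eo: 20.0, isotope_lambda: 0.41}
    - {name: cetyl-EO, base_mass: 242.2610, abundance: 0.12, mean_eo: 20.0, isotope_lambda: 0.39}
  R3:
    - {name: oleyl-EO, base_mass: 268.2766, abundance: 1.0, mean_eo: 20.0, isotope_lambda: 0.41}
    - {name: cetyl-EO, base_mass: 242.2610, abundance: 0.35, mean_eo: 20.0, isotope_lambda: 0.39}
noise_sd: 1.0e-4
replicate_cv: 0.10
abundance_cv: 0.10
mz_range: [500.0, 2400.0]
n_samples_per_class: 8
n_replicates: 4
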