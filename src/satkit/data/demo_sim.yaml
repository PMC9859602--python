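# Small demo genome: two satellite families in AT-rich background.
genome_length: 200000
background_at: 0.59
read_length: 150
coverage: 2.0
seed: 0
families:
  - name: demoA
    monomer_length: 183
    target_proportion: 0.01
    divergence: 0.05
    kappa: 2.0
    n_arrays: 3
    array_length_cv: 0.5
  - name: demoB
    monomer_length: 60
    target_proportion: 0.005
    divergence: 0.15
    kappa: 2.0
    n_arrays: 4
    array_length_cv: 0.5
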