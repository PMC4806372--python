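# Cohort experiment: 13 phantoms, planar mode, all three methods.
cohort_size: 13
base_seed: 0
mode: 2d
methods: [co, sto, bdpc]
prescription_gy: 60.0
fractions: 30
lung_boost_gy: 3.0
output_dir: results/cohort13
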