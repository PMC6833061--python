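# Demo cohort: 30 patients per group, two right-precordial leads, clean
# records (no acquisition noise) for fast, reproducible runs.
n_per_group: [30, 30, 30]
n_beats: 4
leads: [V1, V2]
noise_sd: 0.0
drug_attenuation_fraction: 0.3
seed: 7
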