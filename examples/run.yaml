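# Demo configuration for `tetherloc run` — all inputs are simulated.
seed: 7
out_dir: tetherloc_run
ensemble_n: 2000
angular_step: 25.0
n_particles: 8
handedness_step: 60.0
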