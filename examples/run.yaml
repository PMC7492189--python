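# Full pipeline demo: simulate a small culture, reconstruct every
# snapshot, compute all metrics, compare against null models, and run
# the multifractal analysis.  Override the seed / output directory on
# the command line:  neurocult run-all --config examples/run.yaml --seed 1 --out out/
out_dir: out
seed: 1
mode: neuron
culture:
  field_height_px: 768
  field_width_px: 768
  n_somas: 25
  n_snapshots: 3
  debris_count: 15
  gap_rate: 0.15
  noise_sigma: 0.01
reconstruction:
  gap_radius_px: 12.0
null_models:
  kinds: [RR, ER, WS, BA, SSF, WMG]
  n_realizations: 200
mfa:
  q_min: -10.0
  q_max: 10.0
  q_step: 0.5
  n_covers: 20
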