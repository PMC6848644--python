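# A small end-to-end run: 8 phantoms, 2-fold cross-validation, desk network.
# Usage: nigraseg run-all -c examples/config.yaml --overwrite
seed: 11
output_dir: runs/demo
phantom:
  n_hc: 4
  n_pd: 4
network:
  preset: desk
training:
  preset: desk
  epochs: 2
  folds: 2
quantify:
  k_values: [1.0, 1.5, 2.0]
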