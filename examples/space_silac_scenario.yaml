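# Synthetic forward/reverse SILAC protein-level scenario: heavy-crosslinked
# (forward) and light-crosslinked (reverse) experiments on the same truth.
mode: space_silac
outdir: space_run
seed: 11
simulate:
  n_proteins: 200
  chromatin_fraction: 0.1
  effect_log2fc: 2.0
  design:
    - [forward, "1"]
    - [forward, "2"]
    - [reverse, "1"]
    - [reverse, "2"]
    - [reverse, "3"]
    - [reverse, "4"]
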