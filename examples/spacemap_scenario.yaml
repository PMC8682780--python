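# Synthetic two-fraction (crosslinked vs released) peptide scenario:
# 200 proteins, 10% planted chromatin-binders with contact regions inside
# IDRs, planted enrichment log2FC = 2, three replicates per fraction.
mode: spacemap
outdir: spacemap_run
seed: 11
simulate:
  n_proteins: 200
  chromatin_fraction: 0.1
  effect_log2fc: 2.0
  contact_region_class: IDR
  n_replicates: 3
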