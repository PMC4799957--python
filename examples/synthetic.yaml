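# Default two-species synthetic study: species A plays the experimental
# cohort (18 tumors vs 18 matched nontumor samples), species B the
# comparator cohort whose CNA labels also drive the planted expression
# concordance.  Run with:  crosscna all --config examples/synthetic.yaml
schema_version: 1
seed: 17
outdir: crosscna_out

simulate:
  n_chrom: 2
  genes_per_chrom: 60
  ortholog_rate: 0.8
  probe_spacing: 300000       # bp between probes
  noise_sd: 0.2               # log2-ratio units
  group_sizes_a: {tumor: 18, nontumor: 18}
  group_sizes_b: {tumor: 18, nontumor: 18}
  specs_a:
    - {chromosome: chrA1, start: 2000000, end: 12000000,
       direction: gain, effect: 0.8, penetrance: 0.5, group: tumor}
    - {chromosome: chrA2, start: 20000000, end: 30000000,
       direction: loss, effect: -0.8, penetrance: 0.4, group: tumor}
  specs_b:
    - {chromosome: chrB1, start: 5000000, end: 18000000,
       direction: gain, effect: 0.8, penetrance: 0.5, group: tumor}
    - {chromosome: chrB2, start: 8000000, end: 20000000,
       direction: loss, effect: -0.8, penetrance: 0.4, group: tumor}
  expression:
    n_up: 30
    n_down: 25
    frac_up_in_gain: 0.5
    frac_down_in_loss: 0.5
  qpcr:
    n_control: 5
    n_treated: 18
    fold_changes: {geneX: 3.5, geneY: 1.0, geneZ: 0.5}
    ct_noise_sd: 0.15

segmentation:
  alpha: 0.01
  n_perm_ref: 1000
  min_probes: 2
  lowess_span: 0.3
  gain_threshold: 0.2
  loss_threshold: -0.2

thresholds:
  freq_threshold: 0.15        # recurrent-CNA frequency criterion
  gene_p_threshold: 0.05      # per-gene between-group p criterion
  q_threshold: 0.1            # DE / qPCR FDR significance

n_perm: 1000

groups:
  focal: tumor
  comparator: nontumor
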