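# Demo configuration: a small synthetic genome that exercises every
# pipeline stage in well under five minutes on one CPU.
simulation:
  seed: 7
  n_individuals: 300
  n_variants: 2000
  block_size: 20
  rho_ld: 0.9
  maf_range: [0.05, 0.5]
  variant_spacing_bp: 500
  gwas_sample_size: 50000
  planted_tau:
    active: 2.0e-05
  n_peaks: 400
  n_cell_states: 4
  specificity_fraction: 0.1
  planted_enrichment_pi: 0.8
  n_lead_variants: 30

ldscore:
  window_bp: 100000
  adjusted: false

sldsc:
  n_blocks: 50
  use_weights: true

clump:
  p_threshold: 5.0e-08
  distance_bp: 500000
  min_mac: 10
  min_maf: 0.01
  min_loci: 3
  mhc: null  # the synthetic genome has no MHC locus

cheers:
  r2_threshold: 0.8
  target_state: state_1

compare:
  n_boot: 2000
  specificity_threshold: 0.9

pathways:
  specificity_threshold: 0.9
  max_tss_distance: 10000
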