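# Example pipeline configuration: flat sections per stage.
# CLI flags override config values; the effective config is recorded in
# the run manifest.

community:
  n_subjects: 5
  sites: [PC, DC]            # subset of {TI, PC, DC}
  n_viral_contigs: 500
  n_bacterial_contigs: 200
  viral_length_dist: {meanlog: 8.3, sdlog: 0.8}   # natural-log bp
  mean_phage_genome_bp: 40000
  abundance_dist: {meanlog: 0.0, sdlog: 0.5}
  subject_effect: 0.8        # in [0, 1]; 1.0 = sigma 1 on the log scale
  site_effect: 0.3
  reads_per_sample: 100000
  read_length_bp: 200
  evidence_error_rates:
    fn_inclusion: 0.01       # viral contig carries no inclusion signal
    fp_inclusion: 0.01       # bacterial contig gets a spurious inclusion signal
    fn_exclusion: 0.01       # bacterial contig fires no exclusion signal
    fp_ribosomal: 0.01       # viral contig wrongly gets >=3 ribosomal ORFs
  seed: 0

spike:
  titers: [1.0e+5, 1.0e+6, 1.0e+7]   # pfu/ml
  spike_genome_bp: 135041
  true_viral_load: 6.0e+8            # particles/ml
  spike_reads_total: 1000000

hostcorr:
  pair_rho: 0.8
  host_noise_sdlog: 0.5

triage:
  min_breadth: 0.75
  viral_db_max_evalue: 1.0e-10
  min_pvog_orfs: 3
  min_pvog_per_kb: 2.0
  long_unknown_min_bp: 3000
  min_ribosomal_orfs_exclude: 3
  min_contig_bp: 1001
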