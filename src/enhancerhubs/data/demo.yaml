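# Demo configuration: a small landscape that runs in ~30 s.
# Analysis thresholds keep the published defaults (5 kb / 1 Mb spans,
# PET count >= 2, FDR < 0.05, >= 5 peaks, |dC| < 0.3, 10 kb 4C window).
# The induced-site occupancy gain is set to ~4x the population MAD of
# the condition drift, the regime in which the concentration-matched
# gate retains induced hubs for comparison.
seed: 1
simulate:
  n_chroms: 2
  chrom_length: 1800000
  n_subdomains: 12
  peaks_per_subdomain: 8
  interaction_enrichment: 2.0
  induction_effect: 0.46
  induced_fraction: 0.08
pipeline:
  n_pets: 8000
  fourc_reads: 20000
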