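# Demo pipeline: synthetic nuclei in the three marker-enrichment modes,
# chromocenter PCC analysis, FISH foci counting and both FASTQ assays.
seed: 7
stages: [simulate, pcc, foci, satcount, satmeth]
simulate:
  modes: [colocalized, cloudy, diffuse]
  n_nuclei_per_mode: 15
  fish:
    n_foci_per_nucleus: [0, 1, 2, 3, 4, 5, 7]
  reads:
    n_reads: 2000
    satellite_fraction: 0.1
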