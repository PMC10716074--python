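# Five-scheme comparison at breeding size I, reduced replication.
# Arms share the founder panel, base population and burn-in per replicate.
master_seed: 7
n_cycles: 5
n_replicates: 2
arms:
  - {scheme: trad, size: I}
  - {scheme: drift, size: I}
  - {scheme: trad_up, size: I}
  - {scheme: gs_a, size: I}
  - {scheme: gs_ad, size: I}
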