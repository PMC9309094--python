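# Demo cohort design for `cnaprofiler simulate` (runs in seconds).
# Ten single samples across four archetypes plus four matched
# CNB/surgical pairs with mild contamination noise. Paired entries get
# distinct template seeds so each pair is an independent tumor.
entries:
  - archetype: complex_gain
    count: 3
  - archetype: complex_loss
    count: 3
  - archetype: amplicon_ddls
    count: 2
  - archetype: normal
    count: 2
  - archetype: complex_gain
    count: 1
    template_seed: 11
    noise: &pair_noise
      dropout_rate: 0.05
      boundary_jitter_sd: 10000
      private_rate: 0.2
  - archetype: complex_loss
    count: 1
    template_seed: 12
    noise: *pair_noise
  - archetype: complex_gain
    count: 1
    template_seed: 13
    noise: *pair_noise
  - archetype: gist_like
    count: 1
    noise: *pair_noise
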