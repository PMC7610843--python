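# Within-species replication: both samples drawn from the chimpanzee
# population at different sites. Any detection above alpha is a false
# positive driven by between-site variance.
name: chimp_replication
group_a: &chimp
  name: chimpanzee
  traits:
    - {name: neophobia, beta0: 800, sigma_L: 100, sigma_S: 100, sigma_e: 50}
    - {name: self_control, beta0: 80, sigma_L: 10, sigma_S: 10, sigma_e: 5}
group_b: *chimp
n_per_group: 10
n_reps: 100000
alpha: 0.05
seed: 2026
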