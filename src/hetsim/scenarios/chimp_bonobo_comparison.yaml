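# Between-species comparison: a true neophobia difference of 150 score
# units (1.5x the between-site SD) and an identical self-control
# distribution in both species.
name: chimp_bonobo_comparison
group_a:
  name: chimpanzee
  traits:
    - {name: neophobia, beta0: 800, sigma_L: 100, sigma_S: 100, sigma_e: 50}
    - {name: self_control, beta0: 80, sigma_L: 10, sigma_S: 10, sigma_e: 5}
group_b:
  name: bonobo
  traits:
    - {name: neophobia, beta0: 950, sigma_L: 100, sigma_S: 100, sigma_e: 50}
    - {name: self_control, beta0: 80, sigma_L: 10, sigma_S: 10, sigma_e: 5}
n_per_group: 10
n_reps: 100000
alpha: 0.05
seed: 2026
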