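# Ground truth for the simplest-model (LM0) recovery experiment:
# genetics plus individual environment only, h2 = 0.79.
n_families: 3000
n_counties: 100
sigma2:
  h: 0.79
  e: 0.21
link: probit
target_prevalence: 0.10
seed: 20260925
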