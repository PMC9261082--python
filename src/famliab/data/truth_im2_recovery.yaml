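# Ground truth for the full-interaction (IM2) recovery experiment.
# Variance fractions: h2 = 0.46; additive environment
# f2+c2+s2+p2+e2 = 0.19 with p2 = 0.005; gene-environment interactions
# hf2+hc2+hs2+he2 = 0.35 with hc2 = 0.21. The sub-splits within the
# additive-environment and interaction blocks are this package's fixed
# choices. Prevalence is raised to 10% so desk-scale cohorts carry enough
# cases for stable recovery.
n_families: 8000
n_counties: 150
sigma2:
  h: 0.46
  f: 0.05
  c: 0.03
  s: 0.03
  p: 0.005
  e: 0.075
  hf: 0.06
  hc: 0.21
  hs: 0.04
  he: 0.04
link: probit
target_prevalence: 0.10
seed: 20260925
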