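# The five-model forward-selection suite, simplest first.
# Trace a: LM0 -> LM1 -> IM1 (linear EQI fixed effects).
# Trace b: LM2 -> IM2 (penalized-spline EQI fixed effects).
models:
  - name: LM0
    random_components: [h, e]
    eqi_fixed_form: none
    link: probit
  - name: LM1
    random_components: [h, f, c, s, p, e]
    eqi_fixed_form: linear
    link: probit
  - name: IM1
    random_components: [h, f, c, s, p, e, hf, hc, hs, he]
    eqi_fixed_form: linear
    link: probit
  - name: LM2
    random_components: [h, f, c, s, p, e]
    eqi_fixed_form: spline
    link: probit
  - name: IM2
    random_components: [h, f, c, s, p, e, hf, hc, hs, he]
    eqi_fixed_form: spline
    link: probit
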