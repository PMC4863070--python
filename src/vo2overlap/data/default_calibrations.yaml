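devices:
  douglas_bag:
    coefficients:
    - -0.020049230890580555
    - 0.03633392783881901
    - 0.023432066149696337
    - -0.006016891035149521
    order: 3
    provenance: 'recovered from printed worked examples: positivity-constrained least
      squares over 5 same-system overlap constraints; RMSE = 2.92e-05'
    valid_range:
    - 1.0
    - 4.0
  parvo_2400:
    coefficients:
    - 0.019151011230810026
    - 0.026376209461564378
    order: 1
    provenance: 'recovered from printed worked examples: exact solve of the two same-system
      overlap constraints; max |residual| = 5.55e-17'
    valid_range:
    - 1.0
    - 4.0
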