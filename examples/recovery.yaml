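# Reference parameter-recovery run: 25 + 25 samples, 1.5-fold increase
# of lactate, glycine and phenylalanine in the cases.
seed: 1
simulate:
  groups:
    - {label: case, n: 25}
    - {label: ctrl, n: 25}
  effects:
    lactate: {case: 1.5}
    glycine: {case: 1.5}
    phenylalanine: {case: 1.5}
contrasts:
  - [case, ctrl]
validation:
  k: 7
  n_perm: 200
  alpha: 0.05
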