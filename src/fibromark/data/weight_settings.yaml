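# Six weight settings over the four ranking dimensions. Each row sums to 1.
# default: a-priori weights biased toward the experimental data.
- name: default
  plasma: 0.3
  liver: 0.3
  prior: 0.2
  secreted: 0.2
- name: prior_knowledge
  plasma: 0.0
  liver: 0.0
  prior: 1.0
  secreted: 0.0
- name: balanced
  plasma: 0.2
  liver: 0.2
  prior: 0.4
  secreted: 0.2
- name: liver_plasma_specific
  plasma: 0.5
  liver: 0.5
  prior: 0.0
  secreted: 0.0
- name: liver_specific
  plasma: 0.0
  liver: 1.0
  prior: 0.0
  secreted: 0.0
- name: plasma_specific
  plasma: 1.0
  liver: 0.0
  prior: 0.0
  secreted: 0.0
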