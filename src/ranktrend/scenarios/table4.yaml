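name: table4
alpha: 0.05
sizes_list:
- - 10
  - 10
  - 10
- - 10
  - 15
  - 20
- - 30
  - 20
  - 10
- - 10
  - 20
  - 10
calibration:
  groups:
  - &id001
    family: normal
    mean: 0.0
    sd: 1.0
  - *id001
  - *id001
scenarios:
- name: 'null'
  'null': true
  groups:
  - family: normal
    mean: 1.0
    sd: 1.0
  - family: exponential
    mean: 1.0
  - family: exponential
    mean: 1.0
- name: a
  'null': false
  groups:
  - family: normal
    mean: 1.0
    sd: 1.0
  - family: exponential
    mean: 1.5
  - family: exponential
    mean: 2.0
- name: b
  'null': false
  groups:
  - family: normal
    mean: 1.0
    sd: 1.0
  - family: exponential
    mean: 2.0
  - family: exponential
    mean: 2.0
- name: c
  'null': false
  groups:
  - family: normal
    mean: 1.0
    sd: 1.0
  - family: exponential
    mean: 1.0
  - family: exponential
    mean: 2.0
- name: d
  'null': false
  groups:
  - family: normal
    mean: 1.0
    sd: 1.0
  - family: exponential
    mean: 2.0
  - family: exponential
    mean: 1.5
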