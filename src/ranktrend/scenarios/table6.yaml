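name: table6
alpha: 0.05
sizes_list:
- - 8
  - 8
  - 8
  - 8
- - 10
  - 6
  - 6
  - 10
- - 20
  - 20
  - 10
  - 10
- - 10
  - 20
  - 10
  - 20
calibration:
  groups:
  - &id001
    family: t3
    mean: 0.0
  - *id001
  - *id001
  - *id001
scenarios:
- name: 'null'
  'null': true
  groups:
  - &id002
    family: t3
    mean: 0.0
  - *id002
  - *id002
  - *id002
- name: A
  'null': false
  groups:
  - family: t3
    mean: 0.0
  - family: t3
    mean: 0.2
  - family: t3
    mean: 0.5
  - family: t3
    mean: 1.0
- name: B
  'null': false
  groups:
  - family: t3
    mean: 0.0
  - family: t3
    mean: 0.5
  - family: t3
    mean: 0.5
  - family: t3
    mean: 0.5
- name: C
  'null': false
  groups:
  - family: t3
    mean: 0.0
  - family: t3
    mean: 0.0
  - family: t3
    mean: 0.0
  - family: t3
    mean: 1.0
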