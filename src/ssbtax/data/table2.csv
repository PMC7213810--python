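sex,age_group,beverage,weekly_servings
female,15-24,ssb,1.71
female,15-24,fruit_juice,0.79
female,15-24,milk,1.01
female,25-34,ssb,1.73
female,25-34,fruit_juice,1.52
female,25-34,milk,1.15
female,35-44,ssb,1.7
female,35-44,fruit_juice,1.52
female,35-44,milk,1.31
female,45-54,ssb,1.61
female,45-54,fruit_juice,1.46
female,45-54,milk,1.29
female,55-64,ssb,1.3
female,55-64,fruit_juice,1.3
female,55-64,milk,1.21
female,65+,ssb,0.93
female,65+,fruit_juice,1.2
female,65+,milk,1.25
male,15-24,ssb,1.77
male,15-24,fruit_juice,1.47
male,15-24,milk,0.98
male,25-34,ssb,2.17
male,25-34,fruit_juice,1.32
male,25-34,milk,1.21
male,35-44,ssb,2.05
male,35-44,fruit_juice,1.3
male,35-44,milk,1.31
male,45-54,ssb,1.82
male,45-54,fruit_juice,1.12
male,45-54,milk,1.28
male,55-64,ssb,1.52
male,55-64,fruit_juice,1.11
male,55-64,milk,1.27
male,65+,ssb,1.21
male,65+,fruit_juice,1.22
male,65+,milk,1.3
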