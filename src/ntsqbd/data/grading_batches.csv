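batch_id,Z1,Z2,Z4,Z5,Z6,reported_grade
PN17,6.55,37.1,35.9,7.19,242,low
PN18,8.05,38.7,34.0,7.41,241,high
PN19,8.67,51.6,46.8,7.42,312,low
PN20,9.09,38.7,32.3,6.43,227,high
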