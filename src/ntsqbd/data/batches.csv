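batch_id,Z1,Z2,Z3,Z4,Z5,Z6
PN1,15.9,59.2,7.35,52.9,14.0,363
PN2,8.42,32.1,3.21,30.4,6.99,185
PN3,14.3,53.9,7.74,47.5,11.2,355
PN4,7.18,33.4,4.64,31.3,5.17,216
PN5,14.5,52.7,7.79,51.8,11.0,387
PN6,13.3,52.4,8.37,48.0,11.3,342
PN7,8.31,34.6,4.50,30.4,5.89,192
PN8,10.4,48.6,6.95,43.9,7.89,363
PN9,13.4,49.4,8.27,45.5,10.4,337
PN10,13.3,47.5,7.64,46.6,9.79,356
PN11,8.99,38.5,4.41,29.7,5.03,224
PN12,12.4,46.8,7.83,42.7,9.19,357
PN13,14.5,48.3,6.33,46.3,11.2,304
PN14,8.04,36.0,4.38,29.0,5.07,197
PN15,15.1,51.7,6.42,48.3,13.1,341
PN16,14.8,55.7,7.10,51.3,14.2,316
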