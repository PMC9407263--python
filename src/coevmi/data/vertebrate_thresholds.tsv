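score	480.76	151.52	79.29	45.61	30.18	20.99	15.04	10.93	7.85	6.17	4.62	3.59
percent	99.68	98.43	97.32	95.85	92.23	89.40	85.31	80.93	75.51	69.99	63.81	55.96
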