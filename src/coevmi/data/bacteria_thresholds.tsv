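score	44.40	32.01	23.93	20.14	18.26	17.03	15.00	13.19	11.07	10.43	9.46	8.34	7.09
percent	98.75	96.56	75.58	95.09	90.45	89.89	84.70	79.83	75.61	72.36	66.89	61.25	56.09
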