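time	rpm0	rpm1	rpm2	rpm3	rpm4	rpm5	rpm6	rpm7	rpm8	rpm9	rpm10	rpm11	rpm12
0	5	9	15	24	35	49	63	75	84	91	94	97	98
30	0	5	5	9	15	24	35	63	84	91	94	97	98
60	0	0	0	5	9	15	24	49	75	84	91	97	98
90	0	0	0	0	5	9	15	35	63	84	91	94	97
120	0	0	0	0	0	5	9	24	49	75	84	94	97
150	0	0	0	0	0	0	5	15	35	63	84	91	94
180	0	0	0	0	0	0	0	9	24	49	75	84	94
210	0	0	0	0	0	0	0	5	15	35	63	84	94
240	0	0	0	0	0	0	0	5	9	24	63	75	94
270	0	0	0	0	0	0	0	5	5	15	49	75	91
300	0	0	0	0	0	0	0	5	5	9	49	63	91
330	0	0	0	0	0	0	0	5	5	5	35	63	84
360	0	0	0	0	0	0	0	5	5	5	35	49	84
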