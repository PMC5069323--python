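code	rr_lo	rr_hi	pr_lo	pr_hi	motor
0	0	0	0	0	none
1	1	9	1	40	extends_flexes
2	36	inf	41	60	withdraws
3	25	35	121	inf	localizes
4	10	24	61	120	obeys
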