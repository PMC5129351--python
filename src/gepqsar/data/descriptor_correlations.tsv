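Correlation	NCOS	NNOS	KFBI	BBI	SICI	TEIA	PLPT	LUMO
NCOS	1.000	−0.227	0.649	−0.708	0.667	0.234	−0.034	−0.374
NNOS		1.000	0.175	−0.014	0.159	0.312	−0.201	−0.111
KFBI			1.000	−0.569	0.730	0.433	0.007	−0.18
BBI				1.000	−0.681	−0.259	−0.173	0.438
SICI					1.000	0.620	0.250	−0.456
TEIA						1.000	0.339	−0.107
PLPT							1.000	−0.277
LUMO								1.000
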