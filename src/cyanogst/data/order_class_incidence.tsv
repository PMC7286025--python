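order	Chi	cyGSTX1	cyGSTX2	cyGSTX3	cyGSTX4	cyGSTX5	cyGSTX6	cyGSTX7	cyGSTX8	cyGSTX9	cyGSTX10	cyGSTX11
Pleurocapsales	0	0	0	0	1	1	1	0	0	1	0	0
Chroococcales	1	1	1	1	1	1	1	1	0	0	0	0
Oscillatoriales	1	1	1	1	1	0	1	1	0	0	0	0
Nostocales	1	1	1	1	1	1	0	0	1	0	1	1
Stigonematales	1	1	1	1	1	0	0	0	0	0	0	0
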