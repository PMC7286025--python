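order	Chroococcales	Pleurocapsales	Oscillatoriales	Nostocales	Stigonematales
Chroococcales		0.0619	0.0655	0.0577	0.0609
Pleurocapsales	1.4035		0.0681	0.0598	0.0637
Oscillatoriales	1.3594	1.4166		0.0634	0.0664
Nostocales	1.3054	1.3361	1.3376		0.0582
Stigonematales	1.2731	1.3103	1.2907	1.1904
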