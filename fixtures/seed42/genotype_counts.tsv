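population	AA	AG	GG
Jiulong	7	54	69
Zhongdian	0	7	25
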