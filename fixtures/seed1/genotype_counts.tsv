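population	AA	AG	GG
Jiulong	7	53	70
Zhongdian	1	11	20
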