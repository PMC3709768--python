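position	allele_label	base
53	F_1	G
53	F_2	A
53	M_1	G
53	M_2	A
53	S_1	G
53	cattle	G
204	F_1	T
204	F_2	C
204	M_1	T
204	M_2	C
204	S_1	C
204	cattle	T
407	F_1	G
407	F_2	T
407	M_1	T
407	M_2	T
407	S_1	T
407	cattle	T
689	F_1	A
689	F_2	A
689	M_1	A
689	M_2	A
689	S_1	C
689	cattle	A
700	F_1	A
700	F_2	G
700	M_1	A
700	M_2	G
700	S_1	A
700	cattle	A
896	F_1	A
896	F_2	A
896	M_1	G
896	M_2	G
896	S_1	G
896	cattle	G
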