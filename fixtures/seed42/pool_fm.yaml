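fasta: subunits.fa
h:
- id: Hf
  weight: 0.5
- id: Hm
  weight: 0.5
m:
  id: M
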