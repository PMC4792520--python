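format-version: 1.2
ontology: efo

[Term]
id: EFO:0000001
name: experimental factor

[Term]
id: EFO:0000322
name: cell line
is_a: EFO:0000001

[Term]
id: EFO:0001187
name: HepG2
synonym: "hepatocellular carcinoma cell line" EXACT []
is_a: EFO:0000322

[Term]
id: EFO:0002067
name: K562
is_a: EFO:0000322

[Term]
id: EFO:0001196
name: IMR-90
is_a: EFO:0000322
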