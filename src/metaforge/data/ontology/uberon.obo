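format-version: 1.2
ontology: uberon

[Term]
id: UBERON:0000061
name: anatomical structure

[Term]
id: UBERON:0002097
name: skin of body
is_a: UBERON:0000061

[Term]
id: UBERON:0001003
name: skin epidermis
synonym: "epidermis" EXACT []
is_a: UBERON:0000061
relationship: part_of UBERON:0002097

[Term]
id: UBERON:0002107
name: liver
synonym: "hepatic organ" EXACT []
is_a: UBERON:0000061

[Term]
id: UBERON:0000955
name: brain
is_a: UBERON:0000061

[Term]
id: UBERON:0000948
name: heart
is_a: UBERON:0000061

[Term]
id: UBERON:0002048
name: lung
is_a: UBERON:0000061

[Term]
id: UBERON:0000178
name: blood
is_a: UBERON:0000061

[Term]
id: UBERON:0001264
name: pancreas
is_a: UBERON:0000061
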