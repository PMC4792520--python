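format-version: 1.2
ontology: cl

[Term]
id: CL:0000000
name: cell

[Term]
id: CL:0000066
name: epithelial cell
is_a: CL:0000000

[Term]
id: CL:0000312
name: keratinocyte
synonym: "malpighian cell" EXACT []
is_a: CL:0000066
relationship: part_of UBERON:0001003

[Term]
id: CL:0000182
name: hepatocyte
is_a: CL:0000066
relationship: part_of UBERON:0002107

[Term]
id: CL:0000084
name: T cell
synonym: "T lymphocyte" EXACT []
is_a: CL:0000000
relationship: part_of UBERON:0000178

[Term]
id: CL:0000236
name: B cell
is_a: CL:0000000
relationship: part_of UBERON:0000178
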