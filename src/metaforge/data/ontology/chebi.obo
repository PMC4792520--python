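format-version: 1.2
ontology: chebi

[Term]
id: CHEBI:24431
name: chemical entity

[Term]
id: CHEBI:41774
name: tamoxifen
is_a: CHEBI:24431

[Term]
id: CHEBI:16236
name: ethanol
is_a: CHEBI:24431

[Term]
id: CHEBI:28262
name: dimethyl sulfoxide
is_a: CHEBI:24431
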