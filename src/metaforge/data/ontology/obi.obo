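format-version: 1.2
ontology: obi

[Term]
id: OBI:0000070
name: assay

[Term]
id: OBI:0000716
name: ChIP-seq
synonym: "chromatin immunoprecipitation sequencing" EXACT []
is_a: OBI:0000070

[Term]
id: OBI:0001271
name: RNA-seq
synonym: "transcription profiling by high throughput sequencing" EXACT []
is_a: OBI:0000070

[Term]
id: OBI:0002039
name: ATAC-seq
is_a: OBI:0000070
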