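Meis2	regulation of transcription, DNA-templated
Meis2	eye development
Otx2	regulation of transcription, DNA-templated
Otx2	eye development
Rax	regulation of transcription, DNA-templated
Rax	eye photoreceptor cell differentiation
Ring1	regulation of transcription, DNA-templated
Ring1	eye development
Rorb	regulation of transcription, DNA-templated
Rorb	eye photoreceptor cell development
Vax2	regulation of transcription, DNA-templated
Vax2	eye morphogenesis
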