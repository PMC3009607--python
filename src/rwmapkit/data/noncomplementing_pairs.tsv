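mutation_a	mutation_b	outcome
L5Jcs4	L5Jcs36	F
L5Jcs24	L5Jcs27	F
L5Jcs7	L5Jcs14	F
L5Jcs6	L5Jcs35	F
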