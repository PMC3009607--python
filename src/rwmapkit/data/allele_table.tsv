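allele	gene
L5Jcs1	Tapt1
L5Jcs4	Paxip1
L5Jcs36	Paxip1
L5Jcs5	Tbc1d14
L5Jcs7	Nop14
L5Jcs14	Nop14
L5Jcs11	Tyms
L5Jcs37	Rest
Dumbo	Hmx1
L5Jcs24	Cad
L5Jcs27	Cad
L5Jcs31	Haus3
L5Jcs32	Fbxl5
L5Jcs8	Ugdh
Ste5Jcs1	Nsun7
Deaf5Jcs1	Otof
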