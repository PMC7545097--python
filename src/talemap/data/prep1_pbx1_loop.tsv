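crosslink	peptides	replicates
PREP1(260)(262)	LSILHQDDGSSKNKR(12)(14)
PREP1(102)(105)	KEGKPFFCEDPE(1)(4)
PREP1(334)(335)	KKTAQNRPVQR(1)(2)
PREP1(331)(333)	SSCSETPKTKK(8)(10)
PBX1(292)(293)	YKKNIGK(2)(3)
PBX1(85)(87)	IKEKTVLSIR(2)(4)
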