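crosslink	peptides	replicates
PBX1(85)(87)	IKEKTVLSIR(2)(4)
PBX1(292)(293)	YKKNIGKFQEE(2)(3)
PBX1(293)(297)	YKKNIGKFQEE(3)(7)
MEIS1(270)(271)	PDKDKKR(5)(6)
MEIS1(305)(306)	QKKQLAQD(2)(3)
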