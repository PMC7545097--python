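crosslink	peptides	replicates
MEIS1(195)-PBX1(153)	GGSKSDSEDITR(4)-AKLSQIR(2)
MEIS1(195)-PBX1(242)	EGGSKSDSEDITR(5)-NFNKQATE(4)
MEIS1(178)-PBX1(153)	YISCLKGK(6)-AKLSQIR(2)
MEIS1(161)-PBX1(65)	LEKVHE(3)-KHALNCHR(1)
MEIS1(195)-PBX1(308)	EGGSKSDSEDITR(5)-ANIYAAK(7)
MEIS1(195)-PBX1(297)	EGGSKSDSEDITR(5)-NIGKFQEE(4)
MEIS1(195)-PBX1(87)	EGGSKSDSEDITR(5)-KTVLSIR(1)
MEIS1(161)-PBX1(308)	LEKVHE(3)-ANIYAAK(7)
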