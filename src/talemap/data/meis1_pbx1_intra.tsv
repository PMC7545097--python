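crosslink	peptides	replicates
PBX1(87)-PBX1(195)	KTVLSIR(1)-TRPISPKEIER(7)
PBX1(153)-PBX1(242)	AKLSQIR(2)-NFNKQATE(4)
PBX1(153)-PBX1(308)	AKLSQIR(2)-ANIYAAK(7)
PBX1(297)-PBX1(308)	NIGKFQEE(4)-ANIYAAK(7)
PBX1(242)-PBX1(308)	GGSKSDSEDITR(4)-ANIYAAK(7)
PBX1(195)-PBX1(308)	TRPISPKE(7)-ANIYAAK(7)
PBX1(87)-PBX1(242)	KTVLSIR(1)-NFNKQATE(4)
PBX1(87)-PBX1(153)	KTVLSIR(1)-AKLSQIR(2)
MEIS1(178)-MEIS1(195)	YISCLKGK(6)-GGSKSDSEDITR(4)
MEIS1(126)-MEIS1(132)	DIAVFAKQIR(7)-AEKPLFSSNPE(3)
MEIS1(161)-MEIS1(195)	LEKVHE(3)-EGGSKSDSEDITR(5)
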