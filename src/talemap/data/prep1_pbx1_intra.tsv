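crosslink	peptides	replicates
PBX1(87)-PBX1(195)	KTVLSIR(1)-TRPISPKEIER(7)
PBX1(242)-PBX1(308)	NFNKQATE(4)-EANIYAAK(8)
PBX1(65)-PBX1(195)	KHALNCHR(1)-TRPISPKEIER(7)
PBX1(195)-PBX1(308)	TRPISPKEIER(7)-ANIYAAK(7)
PBX1(153)-PBX1(308)	AKLSQIR(2)-ANIYAAK(7)
PBX1(153)-PBX1(242)	AKLSQIR(2)-NFNKQATE(4)
PBX1(87)-PBX1(308)	KTVLSIR(1)-ANIYAAK(7)
PBX1(87)-PBX1(153)	KTVLSIR(1)-AKLSQIR(2)
PBX1(65)-PBX1(308)	KHALNCHR(1)-ANIYAAK(7)
PBX1(65)-PBX1(74)	KHALNCHR(1)-MKPALFNVLCE(2)
PBX1(65)-PBX1(87)	KHALNCHR(1)-KTVLSIR(1)
PBX1(74)-PBX1(195)	MKPALFNVLCE(2)-TRPISPKE(7)
PREP1(134)-PREP1(140)	LEKVNE(3)-LCKDFCSR(3)
PREP1(140)-PREP1(151)	LCKDFCSR(3)-YIACLKTK(6)
PREP1(134)-PREP1(268)	LEKVNE(3)-GVLPKHATNVMR(5)
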