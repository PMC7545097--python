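crosslink	peptides	replicates
PBX1(87)-PREP1(55)	KTVLSIR(1)-SQTPMDVDKQAIYR(9)	R1;R2
PBX1(308)-PREP1(134)	ANIYAAK(7)-LEKVNE(3)	R1;R2
PBX1(308)-PREP1(268)	ANIYAAK(7)-GVLPKHATNVMR(5)	R1;R2
PBX1(87)-PREP1(73)	KTVLSIR(1)-KCEQSTQGSE(1)	R1;R2
PBX1(308)-PREP1(140)	ANIYAAK(7)-LCKDFCSR(3)	R1;R2
PBX1(153)-PREP1(268)	AKLSQIR(2)-GVLPKHATNVMR(5)	R1;R2
PBX1(65)-PREP1(134)	KHALNCHR(1)-LEKVNE(3)	R1;R2
PBX1(87)-PREP1(25)	KTVLSIR(1)-LKTEQD(2)	R1;R2
PBX1(195)-PREP1(268)	TRPISPKEIER(7)-GVLPKHATNVMR(5)	R1;R2
PBX1(153)-PREP1(151)	AKLSQIR(2)-YIACLKTK(6)	R1;R2
PBX1(65)-PREP1(25)	KHALNCHR(1)-LKTEQDPNCSEPDAE(2)	R1;R2
PBX1(153)-PREP1(153)	AKLSQIR(2)-TKMNSE(2)	R1;R2
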