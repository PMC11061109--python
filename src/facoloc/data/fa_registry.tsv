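symbol	aliases	pfam	interpro	subcomplex
MHF1	CENPS;FAAP16	PF15630	IPR029003	Activation
MHF2	CENPX;FAAP10	PF09415	IPR018552	Activation
FANCA		PF03511	IPR003516	Core complex
FANCB			IPR033333	Core complex
FANCC		PF02106	IPR000686	Core complex
FANCE		PF11510	IPR039685	Core complex
FANCF		PF11107	IPR035428	Core complex
FANCG	XRCC9		IPR039684	Core complex
FANCJ	BRIP1	PF06733	IPR010614	Core complex
FANCL		PF11793	IPR026848	Core complex
FANCM		PF16783	IPR031879	Core complex
FAAP20		PF15750	IPR031490	Core complex
FAAP24		PF17949	IPR026985	Core complex
FAAP100		PF15146	IPR029251	Core complex
FANCT	UBE2T	PF00179	IPR000608	Monoubiquitination
ATR		PF00454	IPR000403	Monoubiquitination
UHRF1		PF02182	IPR047406	Monoubiquitination
UHRF2		PF02182	IPR047468	Monoubiquitination
FANCD2		PF14631	IPR029448	ID complex
FANCI		PF14674;PF14675;PF14676;PF14677;PF14678;PF14679;PF14680	IPR026171	ID complex
SLX1		PF21202	IPR048749	Endonuclease
FANCP	SLX4	PF09494	IPR018574	Endonuclease
FAN1		PF08774	IPR014883	Endonuclease
EME1		PF21292	IPR033310	Endonuclease
MUS81		PF21136	IPR033309	Endonuclease
FANCQ	XPF	PF02732	IPR006167	Endonuclease
ERCC1		PF03834	IPR047260	Endonuclease
FANCS	BRCA1	PF00533	IPR011364	HR and DNA repair
FANCD1	BRCA2	PF09103;PF09104	IPR015525	HR and DNA repair
FANCN	PALB2	PF16756	IPR042417	HR and DNA repair
FANCO	RAD51C	PF08423	IPR013632	HR and DNA repair
FANCR	RAD51	PF08423	IPR011941	HR and DNA repair
FANCU	XRCC2	PF08423	IPR030547	HR and DNA repair
FANCV	REV7	PF02301	IPR003511	HR and DNA repair
FANCW	RFWD3	PF13639	IPR037381	HR and DNA repair
REV1		PF16727	IPR031991	HR and DNA repair
REV3			IPR030559	HR and DNA repair
DPOLN		PF00476	IPR001098	HR and DNA repair
USP1	UBP1	PF00443	IPR033815	Deubiquitination
UAF1	WDR48	PF11816	IPR021772	Deubiquitination
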