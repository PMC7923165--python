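symbol	accession	MCF7	MDA231	DG75	present_in
ARFGAP1	Q8N6T3	X	175		MCF7;MDA231
BLK	P51451			187	MCF7;DG75
CBL	P22681	X	700		MCF7;MDA231;DG75
CDK1	P06493			15	MCF7;MDA231;DG75
CLTA	P09496	X			MCF7;MDA231;DG75
COPS4	Q9BT78	X			MCF7;DG75
COPS8	Q99627	X			MCF7;DG75
DNMT1	P26358		359 ; 399		MDA231
EPS15L1	Q9UBC2	X			MCF7;MDA231
ESPL1	Q14674		719		MCF7;MDA231;DG75
FIP1L1	Q6UN15			113	DG75
GBF1	Q92538		377		MDA231
KPNA4	O00629		66		MDA231
MTMR6	Q9Y217		108		MDA231
NFKB2	Q00653			39 ; 867	MCF7;MDA231;DG75
PTDSS1	P48651		424		MDA231
PYGB	P11216		263		MCF7;MDA231
REEP4	Q9H6H4		172		MDA231
RRP8	O43159			259	DG75
SAP30BP	Q9UHR5		46		MDA231
SF3B1	O75533		38 ; 70		MDA231
SKP1	P63208	X			MCF7;DG75
STAM	Q92783	X			MCF7;MDA231
SUPT5H	O00267		140		MDA231
TFRC	P02786		20		MCF7;MDA231
TRIP10	Q15642	X			MCF7;DG75
TYMS	P04818		153		MCF7;MDA231
UPF1	Q92900		113 ; 1112	113 ; 1112	MCF7;MDA231;DG75
VAMP8	Q9BV40	X			MCF7;MDA231
YAP1	P46937		391 ; 407		MCF7;MDA231
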