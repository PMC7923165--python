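symbol	accession	MCF7	MDA231	DG75
NFKBIE	O00221		155	155
NFATC2	Q13469			752
PTPN6	P29350	X		536
NRAS	P01111	X
RAC1	P63000	X
GRB2	P62993	X
PLCG2	P16885		1217	759 * ; 550 ; 858 ; 1245
BTK	Q06187			551 *
MAPK3	P27361			204
RELA	Q04206	X
SYK	P43405		352
INPPL1	O15357	X		1135
PRKCB	P05771		507
PIK3AP1	Q6ZUJ8			694
CD79A	P11912			210
MAPK1	P28482	X		187
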