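symbol	accession	MCF7	MDA231	DG75
PXN	P49023		409 ; 468	88
WASF2	Q9Y6W5	X
MYL12B	O14950		143
ARHGEF12	Q9NZN5	X	1232
NRAS	P01111	X
ACTN1	P12814	X
RDX	P35241
PPP1R12A	O14974		446 ; 446
CFL2	Q9Y281		89 *	89
ARHGEF7	Q14155	X
PPP1CB	P62140	X
MAPK1	P28482	X		187
ACTB	P60709		240	240
CFL1	P23528		89 *	68 ; 89
GIT1	Q9Y2X7		598 ; 545
PPP1CA	P62136	X
RAC1	P63000	X
EZR	P15311	X	424
IQGAP2	Q13576	X
MAPK3	P27361			204
MYL12A	P19105	X	142
EGFR	P00533		1069
ACTN4	O43707	X
ARHGAP35	Q9NRY4		1087
ACTG1	P63261		240	240
BAIAP2	Q9UQB8		505
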