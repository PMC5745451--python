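symbol	entrez
TAB1	10454
CHUK	1147
CSNK2A2	1459
ERC1	23085
CARD10	29775
IRAK1	3654
LBP	3929
LTA	4049
LTBR	4055
PLCG2	5336
PRKCB	5579
PRKCQ	5588
PTGS2	5743
BTK	695
TNF	7124
TRAF1	7185
TRAF3	7187
TRAF5	7188
TNFSF11	8600
BCL10	8915
CD14	929
CD40	958
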