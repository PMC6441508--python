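# 25-gene cross-platform MSI expression signature (Entrez gene IDs)
# symbols: TNNT1, VNN2, TRIM7, TNFSF9, AGR2, RPL22L1, GNG4, KRT23, ACSL6,
#          TNNC2, SHROOM2, EPDR1, ARID3A, KHDRBS3, GGT7, SHROOM4, MLH1,
#          NKD1, TFCP2L1, VAV3, RUBCNL, ASCL2, AXIN2, PLAGL2, PRR15
7138
8875
81786
8744
10551
200916
2786
25984
23305
7125
357
54749
1820
10656
2686
57477
4292
85407
29842
10451
80183
430
8313
5326
222171
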