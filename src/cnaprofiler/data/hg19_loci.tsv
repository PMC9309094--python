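gene	chrom	start	end
MDM2	12	69201955	69239214
CDK4	12	58141509	58149796
JUN	1	59246462	59249785
MYOCD	17	12569207	12669186
KIT	4	55524084	55606881
NF1	17	29421944	29704695
CDKN2A	9	21967750	21995300
DMD	X	31137344	33229673
ATRX	X	76760355	77041755
TP53	17	7565096	7590856
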