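gene	chrom	start	end
MYCN	2	16080683	16087129
ALK	2	29415640	30144432
LIN28B	6	105404923	105531207
CHD5	1	6161847	6240194
ODC1	2	10580000	10589675
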