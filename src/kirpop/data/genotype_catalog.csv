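genotype_id,2DL1,2DL2,2DL3,2DL4,2DL5,2DS1,2DS2,2DS3,2DS4,2DS5,3DL1,3DL2,3DL3,3DS1,2DP1,3DP1
1,1,0,1,1,0,0,0,0,1,0,1,1,1,0,1,1
6,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
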