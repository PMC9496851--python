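name,cen_motif,tel_motif,2DL1,2DL2,2DL3,2DL4,2DL5,2DS1,2DS2,2DS3,2DS4,2DS5,3DL1,3DL2,3DL3,3DS1,2DP1,3DP1
cA01~tA01,cA01,tA01,1,0,1,1,0,0,0,0,1,0,1,1,1,0,1,1
cA01~tB01 2DS5,cA01,tB01,1,0,1,1,1,1,0,0,0,1,0,1,1,1,1,1
cB02~tB01,cB02,tB01,0,1,0,1,1,1,1,0,0,1,0,1,1,1,0,1
cB02~tA01,cB02,tA01,0,1,0,1,0,0,1,0,1,0,1,1,1,0,0,1
cA01~tB05,cA01,tB05,1,0,1,1,1,1,0,1,0,0,0,1,1,1,1,1
cB01~tA01 2DS3,cB01,tA01,1,1,0,1,1,0,1,1,1,0,1,1,1,0,1,1
cB01~tB01 2DS3,cB01,tB01,1,1,0,1,1,1,1,1,0,1,0,1,1,1,1,1
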