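allele_group,epitopes
C*01,C1
C*03,C1
C*07,C1
C*08,C1
C*12,C1
C*14,C1
C*16,C1;C16
C*02,C2
C*04,C2
C*05,C2
C*06,C2
C*15,C2
C*17,C2
C*18,C2
B*13,Bw4
B*27,Bw4
B*37,Bw4
B*44,Bw4
B*47,Bw4
B*38,Bw4;Bw4-80I
B*49,Bw4;Bw4-80I
B*51,Bw4;Bw4-80I
B*52,Bw4;Bw4-80I
B*53,Bw4;Bw4-80I
B*57,Bw4;Bw4-80I
B*58,Bw4;Bw4-80I
B*59,Bw4;Bw4-80I
A*23,Bw4
A*24,Bw4
A*32,Bw4
A*03,A3
A*11,A11
A*01,
A*02,
A*25,
A*26,
A*29,
A*30,
A*31,
A*33,
A*34,
A*36,
A*66,
A*68,
A*69,
A*74,
B*07,
B*08,
B*14,
B*15,
B*18,
B*35,
B*39,
B*40,
B*41,
B*42,
B*45,
B*46,
B*48,
B*50,
B*54,
B*55,
B*56,
B*60,
B*61,
B*62,
B*64,
B*65,
B*67,
B*70,
B*71,
B*72,
B*73,
B*78,
B*81,
B*82,
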