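# order: self_first
# kind: percent
# rows: self
# n: 775
r1,r2,r3,r4,r5,r6,r7,r8,r9
12,1,0,0,0,0,0,0,0
4,8,1,1,0,0,0,0,0
0,4,7,1,1,0,0,0,0
0,1,3,6,1,0,0,0,0
0,0,0,3,12,1,1,0,0
0,0,0,0,2,6,1,1,0
0,0,0,0,0,2,4,1,1
0,0,0,0,0,0,3,2,1
0,0,0,0,0,0,0,3,5
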