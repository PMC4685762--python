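# order: other_first
# kind: percent
# rows: self
# n: 797
r1,r2,r3,r4,r5,r6,r7,r8,r9
16,3,1,0,1,0,0,0,0
2,9,1,1,0,0,0,0,0
1,2,7,2,1,0,0,0,0
0,1,2,6,1,0,0,0,0
1,1,1,2,11,1,0,0,0
0,0,0,1,3,5,0,0,0
0,0,0,0,1,2,6,0,0
0,0,0,0,0,0,2,2,0
0,0,0,0,1,0,0,1,2
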