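# order: other_first
# kind: percent
# rows: self
# n: 797
r1,r2,r3,r4,r5,r6,r7,r8,r9
12,3,0,0,0,0,0,0,0
2,9,3,0,0,0,0,0,0
1,3,7,2,0,0,0,0,0
0,1,3,6,1,0,0,0,0
0,0,1,3,12,1,1,0,0
0,0,0,0,2,5,1,1,0
0,0,0,0,0,2,3,1,0
0,0,0,0,0,0,2,2,2
0,0,0,0,0,0,1,3,4
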