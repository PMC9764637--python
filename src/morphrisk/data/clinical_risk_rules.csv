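er,her2,grade,nodal,size_gt_cm,risk
*,*,*,>3,,high
0,*,*,1-3,,high
0,*,*,*,1.0,high
*,1,*,1-3,,high
*,1,*,*,1.0,high
1,0,1,0,3.0,high
1,0,1,micro,3.0,high
1,0,2,0,2.0,high
1,0,2,micro,2.0,high
1,0,3,0,1.0,high
1,0,3,micro,1.0,high
1,0,1,1-3,2.0,high
1,0,2,1-3,,high
1,0,3,1-3,,high
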