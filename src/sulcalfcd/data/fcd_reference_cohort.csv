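patient_id,mr_status,lesion_side,n_fcd_sulci,fcd_sulci
1,MR-,left,1,S.C.LPC
2,MR-,left,1,S.C.
3,MR-,left,1,S.F.median
4,MR-,left,1,S.C.
5,MR-,right,1,S.Pe.C.marginal
6,MR-,right,2,S.C.;S.Pe.C.inter
7,MR-,right,2,S.Pe.C.inf;S.Pe.C.inter
8,MR-,right,1,F.I.P.Po.C.inf
9,MR-,right,2,S.Pe.C.marginal;S.Pe.C.median
10,MR-,right,1,S.Pe.C.median
11,MR-,right,3,S.C.;S.Pe.C.sup;S.Pe.C.inter
12,MR+,left,1,S.Pe.C.inter
13,MR+,left,2,S.Pe.C.median;S.Pe.C.marginal
14,MR+,left,2,S.Pe.C.marginal;S.F.median
15,MR+,left,3,S.p.C;S.C.LPC;S.F.median
16,MR+,left,1,S.Pe.C.sup
17,MR+,left,1,S.Pe.C.marginal
18,MR+,left,3,S.Pe.C.inf;S.Pe.C.inter;S.C.sylvian
19,MR+,left,2,S.p.C;S.C.LPC
20,MR+,left,3,S.Pe.C.sup;S.C.;S.Pe.C.marginal
21,MR+,right,3,S.Pe.C.marginal;S.Pe.C.sup;S.Pe.C.median
22,MR+,right,1,S.Pe.C.marginal
23,MR+,right,1,S.F.median
24,MR+,right,2,S.Pe.C.inf;S.C.sylvian
25,MR+,right,1,S.Pe.C.inf
26,MR+,right,1,S.C.
27,MR+,right,1,S.C.
28,MR+,right,1,S.C.
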