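case_id,sex,age,site_class,tissue_origin,grade,preop_therapy,volante,irs,dia_score,treatment,response,response_binary
1,M,63,midgut,primary,G1,"TS1, Octreotide",2,4,769,"Octreotide, UFT",CR,positive
2,F,60,hindgut,primary,G2,Not done,2,6,1492,Lanreotide,SD,positive
3,M,55,midgut,primary,G2,Not done,3,12,1741,Lanreotide,SD,positive
4,M,61,hindgut,primary,G2,Octreotide,1,0,163,Octreotide,SD,positive
5,F,45,hindgut,primary,G1,"Octreotide, Lanreotide",2,2,1075,"Octreotide, Lanreotide",SD,positive
6,M,65,hindgut,primary,G2,Not done,2,4,898,"Octreotide, Lanreotide",SD,positive
7,M,48,hindgut,metastatic_liver,G2,"Octreotide, Lanreotide",2,2,830,"Octreotide, Lanreotide",PD,negative
8,M,72,midgut,metastatic_liver,G2,"Octreotide, Lanreotide",2,4,731,"Octreotide, Lanreotide",PD,negative
9,M,61,foregut,primary,G2,Not done,2,12,2379,Octreotide,PD,negative
10,M,73,foregut,metastatic_liver,G2,Not done,1,0,215,Lanreotide,PD,negative
11,M,74,midgut,primary,G1,Not done,2,8,1240,Lanreotide,SD,positive
12,F,65,foregut,metastatic_liver,G1,Octreotide,2,8,1467,Octreotide,SD,positive
13,F,67,midgut,primary,G1,"Octreotide, Everolimus",2,2,967,Octreotide,SD,positive
14,F,71,hindgut,primary,G2,Not done,2,4,1027,"5FU, CDDP, Octreotide",SD,positive
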