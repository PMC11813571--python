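singer_id,year,score
1,2011,-1.1223
2,2011,1.0589
3,2011,0.3079
4,2011,-0.1308
5,2011,-0.7773
6,2011,0.7445
8,2012,-1.0129
9,2012,-1.4898
10,2012,-1.9019
11,2012,-2.6698
15,2012,-0.5086
16,2013,3.6689
17,2013,0.6905
19,2013,1.3559
20,2013,1.6423
21,2013,1.5903
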