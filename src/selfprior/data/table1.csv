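no,gender,age,duration_years,stage,updrs_iii,mmse,acer,lde
1,M,74,16,2,20,30,98,620
2,F,76,10,2,26,29,91,560
3,M,81,15,2.5,13,29,94,410
4,M,54,15,1,13,29,89,1817
5,F,73,13,2.5,16,28,95,565
6,F,76,9,3,37,30,91,855
7,F,81,13,2,15,29,97,1355
8,M,77,13,2,24,30,97,1722
9,M,64,6,1.5,21,29,94,1175
10,M,48,6,2.5,16,29,88,536
11,M,72,26,1,21,28,85,460
12,M,69,10,1,21,23,84,276
13,M,57,14,1,31,28,94,1180
14,F,66,17,2,19,27,95,1740
15,M,76,12,1,18,27,87,1500
16,F,64,11,3,16,28,96,1000
17,M,77,9,3,19,27,88,700
18,F,55,8,2,20,29,98,200
19,M,56,11,3,14,29,86,1210
20,M,63,11,1.5,16,29,94,1315
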