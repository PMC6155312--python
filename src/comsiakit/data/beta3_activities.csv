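id,ec50_b1_nM,ec50_b2_nM,ec50_b3_nM,pec50_b3_printed,role
1,1.9,25,5.50,8.260,test
2,47,330,223,6.650,train
3,1700,290,21.38,7.670,test
4,21,66,0.89,9.051,train
5,6.6,29,0.56,9.252,train
6,6.6,54,0.78,9.108,train
7,6.8,19,1.32,8.879,train
8,19,180,1.74,8.759,train
9,18,44,0.21,9.678,train
10,7.3,26,0.60,9.222,train
11,5.6,20,0.28,9.553,test
12,6.2,40,0.51,9.292,train
13,3.1,72,0.87,9.060,train
14,1.3,22,0.26,9.585,train
15,1.2,49,0.65,9.187,test
16,7.2,58,1.20,8.921,train
17,13,26,0.48,9.319,test
18,19,13,0.55,9.260,test
19,69,120,162,6.790,train
20,10,170,1.20,8.921,train
21,36,160,36.31,7.440,train
22,9.6,45,10.00,8.000,train
23,7.6,44,2.95,8.530,train
24,22,32,4.47,8.350,train
25,44,53,1.00,9.000,train
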