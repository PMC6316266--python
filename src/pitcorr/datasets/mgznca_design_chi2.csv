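case,gamma,psi,beta,Ku,chi2
1,2.6,5.1,5.1,0.001,1.42
2,2.6,2.6,5.1,0.1005,0.43
3,2.6,0.1,5.1,0.2,1409.05
4,0.1,0.1,5.1,0.1005,342.21
5,5.1,2.6,5.1,0.2,6.31
6,2.6,0.1,5.1,0.001,703.62
7,0.1,2.6,5.1,0.2,0.96
8,5.1,0.1,5.1,0.1005,460.68
9,2.6,2.6,0.1,0.001,0.59
10,2.6,5.1,10.1,0.1005,1.52
11,2.6,2.6,10.1,0.001,1.16
12,2.6,0.1,10.1,0.1005,1096.31
13,2.6,2.6,5.1,0.1005,0.43
14,0.1,2.6,0.1,0.1005,0.42
15,0.1,5.1,5.1,0.1005,1.67
16,2.6,2.6,5.1,0.1005,0.43
17,0.1,2.6,5.1,0.001,0.36
18,2.6,0.1,0.1,0.1005,634.60
19,5.1,2.6,5.1,0.001,6.41
20,2.6,5.1,5.1,0.2,1.71
21,5.1,2.6,0.1,0.1005,0.68
22,5.1,5.1,5.1,0.1005,0.59
23,2.6,2.6,0.1,0.2,0.56
24,5.1,2.6,10.1,0.1005,0.47
25,0.1,2.6,10.1,0.1005,0.47
26,2.6,5.1,0.1,0.1005,0.70
27,2.6,2.6,10.1,0.2,0.32
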