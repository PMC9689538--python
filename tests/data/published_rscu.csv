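# Published per-gene RSCU values for five chronic-periodontitis-associated
# human genes, used as an external data check: every synonymous family must
# sum to its size (up to 3-decimal rounding) and the usage classifier must
# reproduce the over/under-representation calls.
codon,amino_acid,NIN,ABHD12B,WHAMM,AP3B2,SIGLEC5
TTT,F,1.395,1.524,1.267,0.571,0.566
TTC,F,0.605,0.476,0.733,1.429,1.434
TTA,L,0.790,0.816,0.859,0.068,0.114
TTG,L,0.895,0.893,1.284,0.239,0.321
CTT,L,1.019,1.106,0.936,0.329,0.712
CTC,L,0.872,0.553,0.779,0.977,1.594
CTA,L,0.468,0.512,0.709,0.318,0.093
CTG,L,1.956,2.120,1.432,4.070,3.167
ATT,I,1.194,1.669,1.258,1.296,0.335
ATC,I,0.786,1.038,0.842,1.348,2.248
ATA,I,1.021,0.293,0.901,0.356,0.418
GTT,V,0.806,1.425,1.120,0.390,0.553
GTC,V,0.851,1.069,0.808,0.827,1.364
GTA,V,0.704,0.315,0.438,0.422,0.298
GTG,V,1.639,1.190,1.634,2.361,1.786
TCT,S,1.584,1.861,1.722,0.835,0.646
TCC,S,1.068,0.233,1.179,1.508,2.378
TCA,S,0.800,0.297,1.013,0.684,0.402
TCG,S,0.076,0.630,0.260,0.316,0.629
AGT,S,1.133,1.796,0.881,1.171,0.090
AGC,S,1.339,1.184,0.944,1.486,1.856
CCT,P,1.043,0.873,1.083,1.183,0.807
CCC,P,0.979,1.660,0.645,1.827,1.816
CCA,P,1.534,1.335,1.542,0.872,1.035
CCG,P,0.443,0.132,0.729,0.118,0.343
ACT,T,1.071,0.749,1.130,0.597,0.176
ACC,T,0.990,0.783,1.209,2.507,2.299
ACA,T,1.447,2.153,1.593,0.726,0.854
ACG,T,0.491,0.315,0.068,0.171,0.672
GCT,A,1.076,0.902,1.695,0.923,1.236
GCC,A,1.060,1.280,0.986,1.984,2.031
GCA,A,1.347,1.634,0.534,0.540,0.599
GCG,A,0.517,0.184,0.785,0.554,0.135
TAT,Y,1.247,1.449,1.250,0.370,0.720
TAC,Y,0.753,0.551,0.750,1.630,1.280
CAT,H,1.143,0.632,0.794,0.444,0.628
CAC,H,0.857,1.368,1.206,1.556,1.372
CAA,Q,0.657,0.429,0.749,0.381,0.658
CAG,Q,1.343,1.571,1.251,1.619,1.342
AAT,N,1.140,0.927,1.087,0.617,0.555
AAC,N,0.860,1.073,0.913,1.383,1.445
AAA,K,1.023,0.803,1.356,0.543,0.549
AAG,K,0.977,1.197,0.644,1.457,1.451
GAT,D,1.086,1.042,1.229,0.702,0.862
GAC,D,0.914,0.958,0.771,1.298,1.139
GAA,E,1.072,1.180,1.273,0.424,0.309
GAG,E,0.928,0.820,0.727,1.576,1.691
TGT,C,1.021,0.973,1.196,1.464,0.687
TGC,C,0.979,1.027,0.804,0.536,1.313
CGT,R,0.594,1.005,0.560,0.829,0.196
CGC,R,0.344,0.479,0.691,1.249,1.321
CGA,R,0.628,0.123,0.501,0.715,0.534
CGG,R,0.929,0.882,1.088,1.706,0.677
AGA,R,1.752,2.353,2.009,0.447,1.805
AGG,R,1.753,1.157,1.151,1.053,1.467
GGT,G,0.968,0.628,1.034,0.406,0.542
GGC,G,0.988,0.946,1.547,2.069,1.178
GGA,G,1.036,1.135,0.770,0.698,0.935
GGG,G,1.009,1.291,0.649,0.828,1.346
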