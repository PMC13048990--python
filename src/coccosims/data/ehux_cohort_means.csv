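sample_id,kind,n,na_ion,na_ion_se,na_letter,mg_ion,mg_ion_se,mg_letter,k_ion,k_ion_se,k_letter,sr_ion,sr_ion_se,sr_letter,ba_ion,ba_ion_se,ba_letter,na_molar,na_molar_se,mg_molar,mg_molar_se,sr_molar,sr_molar_se,ba_molar,ba_molar_se
C1,culture,43,0.437,0.003,c,0.0295,0.0004,c,0.307,0.005,a,0.0842,0.0002,a,0.00168,0.00001,b,11.14,0.09,4.29,0.05,2.658,0.005,0.0245,0.0002
C2,culture,32,0.61,0.006,b,0.059,0.003,a,0.102,0.006,c,0.0781,0.0002,b,0.000423,0.000009,e,15.6,0.1,8.6,0.4,2.464,0.005,0.0062,0.0001
C3,culture,18,0.8,0.02,b,0.0321,0.0007,abc,0.42,0.04,ab,0.0811,0.0003,ab,0.00096,0.00002,c,20.5,0.6,4.7,0.1,2.56,0.01,0.014,0.0002
C4,culture,36,0.629,0.005,b,0.0298,0.0005,c,0.164,0.005,b,0.0798,0.0001,b,0.00286,0.00002,a,16,0.1,4.34,0.008,2.52,0.003,0.0416,0.0003
C5,culture,22,0.676,0.005,b,0.0295,0.0003,bc,0.117,0.003,bc,0.0764,0.0002,b,0.000594,0.000005,d,17.2,0.1,4.3,0.04,2.411,0.007,0.00865,0.00008
C6,culture,27,1.34,0.02,a,0.045,0.001,ab,0.344,0.009,a,0.0784,0.0002,b,0.00073,0.00001,d,34.2,0.5,6.5,0.1,2.474,0.006,0.0107,0.0002
BS-2,field,28,0.129,0.002,q,0.0068,0.0002,qr,,,,0.0936,0.0005,n,,,,3.28,0.05,0.99,0.03,2.95,0.02,,
EM-2,field,9,1.35,0.04,o,0.0252,0.0008,op,,,,0.1126,0.0004,m,,,,35,1,3.7,0.1,3.55,0.01,,
EM-6,field,11,0.306,0.008,p,0.026,0.003,pq,,,,0.1094,0.0005,m,,,,7.8,0.2,3.8,0.5,3.45,0.02,,
WM-1,field,9,0.34,0.01,p,0.0044,0.0007,r,,,,0.107,0.001,m,,,,8.6,0.3,0.6,0.1,3.37,0.03,,
WM-7,field,7,2.7,0.2,n,0.049,0.004,no,,,,0.0949,0.0006,mn,,,,69,5,7.2,0.6,3,0.02,,
WM-9,field,9,2.9,0.2,n,0.24,0.02,m,,,,0.091,0.002,n,,,,74,6,34,3,2.88,0.06,,
WM-10,field,9,4.4,0.1,m,0.132,0.009,mn,,,,0.0918,0.0009,n,,,,113,3,19,1,2.9,0.03,,
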