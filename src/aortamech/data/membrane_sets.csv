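set_id,label,group,Ri_mm,c_kPa,k1_kPa,k2,beta_deg,lam,Fred_est_N
1,F49,hg,6.3,3.53,21.38,4.24,31.25,1.3675,0.85
2,M60,hg,6.6,6.84,16.70,2.92,38.63,1.1948,1.13
3,M61b,hg,7.7,7.88,16.69,10.23,32.94,1.2400,1.20
4,M66,hg,7.0,16.85,33.98,8.47,37.11,1.0918,1.13
5,M70a,hg,7.3,4.04,67.00,6.82,29.74,1.3412,1.86
6,M70b,hg,7.7,11.69,25.54,24.08,32.67,1.1644,1.17
7,F50,lc,7.2,2.15,53.94,8.27,23.21,1.6869,0.77
8,F65,lc,6.7,0.32,10.84,6.25,9.56,4.3363,0.84
9,M57,lc,8.8,0.39,7.93,6.59,9.67,4.3654,1.26
10,M61a,lc,7.2,0.19,75.80,32.36,6.01,5.8890,0.98
11,M67a,lc,7.5,0.18,46.77,20.74,6.46,5.5922,1.27
12,M67b,lc,7.9,0.18,57.97,6.51,7.85,4.9535,1.05
13,M71,lc,9.9,0.16,87.93,8.39,7.08,5.2656,1.80
14,M77,lc,6.0,0.29,5.93,22.21,8.08,4.6043,1.00
15,F63,cs,5.2,13.64,41.97,3.25,41.43,1.0918,0.58
16,M38,cs,5.2,12.26,19.55,3.09,41.44,1.1272,0.69
17,,cs,10.3,35.33,6.42,43.22,35.87,1.0519,2.58
18,,cs,14.8,66.37,21.16,10.46,45.55,1.0290,4.46
19,,cs,5.3,74.78,61.92,57.51,33.51,1.0211,0.62
20,,cs,3.9,91.05,57.02,33.92,36.71,1.0215,0.27
21,,cs,12.4,29.58,17.53,2.90,51.18,1.0457,4.57
Clinic,,clinic,7.12,102.70,8.35,150.65,42.35,1.042,
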