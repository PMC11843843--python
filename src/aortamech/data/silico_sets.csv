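set_id,label,group,R_mm,H_mm,Phi0_deg,c_kPa,k1_kPa,k2,beta_deg,lam,Fred_mean_N
1,F49,hg,5.9,1.51,252.00,2.31,20.06,4.11,39.95,1.1699,0.57
2,M60,hg,6.3,1.69,156.00,5.91,17.57,3.18,43.16,1.1217,0.83
3,M61b,hg,7.3,1.62,335.00,6.98,11.37,8.05,41.95,1.1039,0.67
4,M66,hg,7.2,1.78,253.00,17.78,25.72,7.65,38.85,1.1385,1.49
5,M70a,hg,7.1,1.23,208.00,2.78,67.45,7.02,35.49,1.1908,0.60
6,M70b,hg,7.4,1.64,201.00,12.18,17.31,22.86,39.69,1.0582,0.52
7,F50,lc,6.7,1.14,323.00,0.68,49.54,7.44,36.67,1.1791,0.41
8,F65,lc,6.2,1.21,248.00,0.05,9.06,5.87,39.36,1.1932,0.36
9,M57,lc,7.5,1.28,322.00,0.05,4.37,4.87,41.11,1.2080,0.55
10,M61a,lc,7.7,1.22,270.00,0.05,49.45,26.74,37.55,1.0836,0.25
11,M67a,lc,8.0,1.58,118.00,0.05,41.95,22.00,38.18,1.0666,0.34
12,M67b,lc,7.9,1.26,174.00,0.05,61.02,7.02,35.49,1.1984,0.56
13,M71,lc,10.0,1.72,118.00,0.05,94.49,9.26,37.65,1.0964,0.84
14,M77,lc,7.0,1.50,135.00,0.05,26.65,39.30,38.23,1.0500,0.19
15,F63,cs,5.4,0.96,96.00,13.59,41.78,3.29,39.86,1.1594,0.74
16,M38,cs,5.3,1.22,117.00,12.20,19.28,3.22,41.60,1.1576,0.74
17,,cs,10.1,2.81,46.19,32.68,7.44,47.90,40.02,1.0210,0.65
18,,cs,14.9,2.81,52.23,67.39,22.53,11.79,47.47,1.0489,5.95
19,,cs,5.3,1.41,20.98,75.91,71.16,67.08,37.06,1.0422,1.03
20,,cs,3.9,0.68,28.81,90.87,64.35,38.12,39.33,1.0281,0.29
21,,cs,12.3,3.54,81.75,28.89,21.33,3.29,53.24,1.0372,3.18
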