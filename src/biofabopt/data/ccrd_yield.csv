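std,run,role,pH,collagen_mg_ml,time_h,temp_c,yield_mg_ml,split
17,1,axial,5,12,72,35,4.91,training
5,2,factorial,6,8,96,30,6.11,training
8,3,factorial,8,16,96,30,9.80,training
1,4,factorial,6,8,48,30,5.66,training
20,5,axial,7,20,72,35,10.92,validation
3,6,factorial,6,16,48,30,10.50,training
2,7,factorial,8,8,48,30,7.10,training
14,8,factorial,8,8,96,40,5.92,training
16,9,factorial,8,16,96,40,7.82,training
13,10,factorial,6,8,96,40,4.60,training
23,11,axial,7,12,72,25,9.82,training
7,12,factorial,6,16,96,30,8.92,training
21,13,axial,7,12,24,35,8.99,training
24,14,axial,7,12,72,45,7.11,training
25,15,center,7,12,72,35,11.82,validation
9,16,factorial,6,8,48,40,5.33,training
11,17,factorial,6,16,48,40,9.23,training
10,18,factorial,8,8,48,40,6.35,validation
15,19,factorial,6,16,96,40,7.25,training
29,20,center,7,12,72,35,11.70,training
30,21,center,7,12,72,35,11.51,validation
12,22,factorial,8,16,48,40,9.42,validation
19,23,axial,7,4,72,35,4.58,training
18,24,axial,9,12,72,35,6.98,validation
26,25,center,7,12,72,35,11.76,training
27,26,center,7,12,72,35,11.56,training
4,27,factorial,8,16,48,30,10.43,training
28,28,center,7,12,72,35,11.62,training
6,29,factorial,8,8,96,30,7.21,training
22,30,axial,7,12,120,35,7.23,training
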