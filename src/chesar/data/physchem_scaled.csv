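compound,MW,clogP,HBD,HBA,RB,PSA
CD 2F,4.83425,0.376,1,2,5,3.312
CD 3F,4.83425,0.376,1,2,5,3.312
CD 4F,4.83425,0.376,1,2,5,3.312
CD 3CF3,5.33433,1.111,1,2,6,3.312
CD 4CF3,5.33433,1.111,1,2,6,3.312
"CD 3,5F",5.01416,0.519,1,2,5,3.312
"CD 3,4F",5.01416,0.519,1,2,5,3.312
"CD 2,3F",5.01416,0.519,1,2,5,3.312
"CD 2,4F",5.01416,0.519,1,2,5,3.312
"CD 2,6F",5.01416,0.519,1,2,5,3.312
CD 3OCF3,5.49432,1.664,1,3,7,4.235
CD 4OCF3,5.49432,1.664,1,3,7,4.235
CD 2F-6CF3,5.51424,1.625,1,2,6,3.312
CD 2F-4Br,5.62321,1.145,1,2,5,3.312
CD 2Cl-6F,5.1787,0.98,1,2,5,3.312
DHCD,3.76319,2.975,1,3,3,3.636
DHCD Bzl,4.6616,0.537,1,2,5,3.312
DHCD 3F,4.85441,0.68,1,2,5,3.312
DHCD 4F,4.85441,0.68,1,2,5,3.312
DHCD 3CF3,5.341493,1.415,1,2,6,3.312
DHCD 4CF3,5.341493,1.415,1,2,6,3.312
DHCD 3OCF3,5.550144,1.968,1,3,7,4.235
DHCD 4OCF3,5.550144,1.968,1,3,7,4.235
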