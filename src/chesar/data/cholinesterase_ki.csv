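compound,series,substituent,Ki_BChE_uM,Ki_BChE_se,Ki_AChE_uM,Ki_AChE_se,SI_printed
CD Bzl,CD,Bzl,0.075,0.007,15,2,200
CD 2F,CD,2F,0.82,0.03,33,1,40
CD 3F,CD,3F,0.075,0.005,40,2,533
CD 4F,CD,4F,1.5,0.1,69,3,46
CD 3CF3,CD,3CF3,2.4,0.1,34,1,14
CD 4CF3,CD,4CF3,2.0,0.1,21,1,11
"CD 3,5F",CD,"3,5F",0.081,0.01,10,1,123
"CD 3,4F",CD,"3,4F",1.3,0.1,13,1,10
"CD 2,3F",CD,"2,3F",0.75,0.03,19,1,25
"CD 2,4F",CD,"2,4F",6.1,0.5,6.4,0.3,1.1
"CD 2,6F",CD,"2,6F",9.9,0.4,7.7,0.5,0.77
CD 3OCF3,CD,3OCF3,7.4,0.4,8.2,1.1,1.1
CD 4OCF3,CD,4OCF3,7.6,0.5,7.3,0.5,0.96
CD 2F-6CF3,CD,2F-6CF3,5.7,0.6,35,4,6.1
CD 2F-4Br,CD,2F-4Br,0.68,0.05,7.2,0.4,10
CD 2Cl-6F,CD,2Cl-6F,5.0,0.3,9.9,0.8,1.9
CN Bzl,CN,Bzl,2.9,0.3,121,12,42
CN 2F,CN,2F,2.4,0.1,80,2,33
CN 3F,CN,3F,6.1,0.3,13,0.4,2.1
CN 4F,CN,4F,2.6,0.1,3.9,0.2,1.5
CN 3CF3,CN,3CF3,4.4,0.2,59,2,13
CN 4CF3,CN,4CF3,6.0,0.3,31,1,5.2
"CN 3,5F",CN,"3,5F",6.3,0.2,34,3,5.4
"CN 3,4F",CN,"3,4F",6.1,0.2,14,0.2,2.3
"CN 2,3F",CN,"2,3F",9.6,0.4,46,3,4.8
"CN 2,4F",CN,"2,4F",6.0,0.2,27,1,4.5
"CN 2,6F",CN,"2,6F",5.2,0.2,30,2,5.8
CN 3OCF3,CN,3OCF3,4.7,0.2,41,2,8.7
CN 4OCF3,CN,4OCF3,7.8,0.3,19,2,2.4
CN 2F-6CF3,CN,2F-6CF3,7.7,0.4,61,2,7.9
CN 2F-4Br,CN,2F-4Br,5.5,0.3,16,1,2.9
CN 2Cl-6F,CN,2Cl-6F,1.2,0.0,17,1,14
DHCD,DHCD,parent,19,2,206,6,11
DHCD Bzl,DHCD,Bzl,0.4,0.02,4.8,0.4,12
DHCD 3F,DHCD,3F,0.3,0.02,27,2,84
DHCD 4F,DHCD,4F,4.3,0.2,31,1,8
DHCD 3CF3,DHCD,3CF3,1.4,0.1,25,1,18
DHCD 4CF3,DHCD,4CF3,3.2,0.2,15,1,5
DHCD 3OCF3,DHCD,3OCF3,6.8,0.3,36,1,5
DHCD 4OCF3,DHCD,4OCF3,5.9,0.2,17,1,3
DHCN,DHCN,parent,1.2,0.1,43,2,43
DHCN Bzl,DHCN,Bzl,0.9,0.04,21,1,23
DHCN 3F,DHCN,3F,1.2,0.1,20,1,20
DHCN 4F,DHCN,4F,1.6,0.1,64,2,40
DHCN 3CF3,DHCN,3CF3,1.2,0.05,41,2,34
DHCN 4CF3,DHCN,4CF3,1.6,0.1,18,1,9
DHCN 3OCF3,DHCN,3OCF3,1.3,0.5,68,1,52
DHCN 4OCF3,DHCN,4OCF3,2.2,0.1,22,1,10
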