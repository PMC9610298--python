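pair,substituent,enzyme,ratio_printed
CN/CD,2F,BChE,2.9
CN/CD,2F,AChE,2.4
CN/CD,3F,BChE,81
CN/CD,3F,AChE,0.33
CN/CD,4F,BChE,1.7
CN/CD,4F,AChE,0.056
CN/CD,3CF3,BChE,1.8
CN/CD,3CF3,AChE,1.7
CN/CD,4CF3,BChE,3.0
CN/CD,4CF3,AChE,1.5
CN/CD,"3,5F",BChE,78
CN/CD,"3,5F",AChE,3.4
CN/CD,"3,4F",BChE,4.7
CN/CD,"3,4F",AChE,1.1
CN/CD,"2,3F",BChE,13
CN/CD,"2,3F",AChE,2.4
CN/CD,"2,4F",BChE,1.0
CN/CD,"2,4F",AChE,4.2
CN/CD,"2,6F",BChE,0.53
CN/CD,"2,6F",AChE,3.9
CN/CD,3OCF3,BChE,0.64
CN/CD,3OCF3,AChE,5
CN/CD,4OCF3,BChE,1.0
CN/CD,4OCF3,AChE,2.6
CN/CD,2F-6CF3,BChE,1.4
CN/CD,2F-6CF3,AChE,1.7
CN/CD,2F-4Br,BChE,8.1
CN/CD,2F-4Br,AChE,2.2
CN/CD,2Cl-6F,BChE,0.24
CN/CD,2Cl-6F,AChE,1.7
DHCN/DHCD,parent,BChE,0.063
DHCN/DHCD,parent,AChE,0.21
DHCN/DHCD,Bzl,BChE,2.2
DHCN/DHCD,Bzl,AChE,4.4
DHCN/DHCD,3F,BChE,4.0
DHCN/DHCD,3F,AChE,0.74
DHCN/DHCD,4F,BChE,0.37
DHCN/DHCD,4F,AChE,2.1
DHCN/DHCD,3CF3,BChE,0.86
DHCN/DHCD,3CF3,AChE,1.6
DHCN/DHCD,4CF3,BChE,0.50
DHCN/DHCD,4CF3,AChE,1.2
DHCN/DHCD,3OCF3,BChE,0.19
DHCN/DHCD,3OCF3,AChE,1.9
DHCN/DHCD,4OCF3,BChE,0.37
DHCN/DHCD,4OCF3,AChE,1.3
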