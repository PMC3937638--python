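name,N,Kb_1e5,dG,dH,TdS,percent_printed
HA10^AN,1.01,61.2,-9.19,-7.57,1.62,113
HA8^NA,0.97,102.3,-9.56,-6.90,2.66,188
HA8^AN,1.00,54.3,-9.16,-8.01,1.15,100
HA7^NN,0.93,36.8,-8.96,-11.26,-2.30,67.8
HA7^AA,0.98,39.2,-9.00,-10.03,-1.03,72.2
HA6^NA,0.89,7.0,-7.96,-11.29,-3.33,12.9
HA6^AN,1.00,5.8,-7.77,-5.40,2.37,10.6
HA5^NN,1.03,5.9,-7.87,-15.25,-7.38,10.8
HA5^AA,1.01,2.9,-7.35,-7.06,0.30,5.3
HA4^AN,1.0,0.22,,,,0.4
C4HA4,0.91,33.0,-8.87,-7.65,1.22,60.8
HA4C4,0.96,49.7,-9.13,-7.02,2.11,91.4
C8,0.97,11.0,-8.22,-6.27,1.95,20.2
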