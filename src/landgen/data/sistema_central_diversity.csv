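population,n,Na,PA,A,Ho,He,Fis
NAJ,20,44,2,4.86,0.66,0.65,-0.01
MOR,20,47,2,5.10,0.74,0.68,-0.08
PEN,20,38,0,4.30,0.48,0.54,0.10
SES,20,50,4,5.46,0.71,0.70,-0.01
CAM,20,48,3,5.19,0.57,0.68,0.16
ZON,20,41,3,4.42,0.65,0.67,0.03
RUI,20,55,5,5.80,0.60,0.72,0.17
AGI,20,57,7,6.05,0.54,0.76,0.29
NEG,20,53,5,5.59,0.45,0.72,0.37
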