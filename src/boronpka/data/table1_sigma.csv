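substituent,position,sigma
OH,meta,0.12
OH,para,-0.37
F,meta,0.34
F,para,0.06
Cl,meta,0.37
Cl,para,0.23
Br,meta,0.39
Br,para,0.23
I,meta,0.35
I,para,0.18
CN,meta,0.56
CN,para,0.66
CH3,meta,-0.07
CH3,para,-0.17
OCH3,meta,0.12
OCH3,para,-0.27
CHO,meta,0.35
CHO,para,0.42
COCH3,meta,0.38
COCH3,para,0.50
NO2,meta,0.71
NO2,para,0.78
CF3,meta,0.43
CF3,para,0.54
OCF3,meta,0.38
OCF3,para,0.35
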