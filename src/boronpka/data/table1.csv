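substituent,position,family,pka,source,approximate
H,parent,benzoic,4.21,25,0
H,parent,benzoic,4.16,28,0
H,parent,boronic,8.9,29,0
H,parent,boronic,8.7,30,0
H,parent,boronic,8.64,31,0
H,parent,boronic,8.86,32,0
H,parent,boronic,8.72,21,0
H,parent,boronic,8.90,33,0
H,parent,boronic,8.70,34,0
OH,ortho,benzoic,2.85,28,0
OH,meta,benzoic,4.09,25,0
OH,meta,benzoic,3.94,28,0
OH,para,benzoic,4.59,25,0
OH,para,benzoic,4.48,28,0
OH,meta,boronic,8.55,35,0
F,ortho,benzoic,3.27,36,0
F,meta,benzoic,3.88,25,0
F,para,benzoic,4.16,25,0
F,ortho,boronic,7.83,37,0
F,ortho,boronic,7.89,38,0
F,ortho,boronic,7.85,38,0
F,ortho,boronic,8.7,39,0
F,meta,boronic,7.50,37,0
F,meta,boronic,8.09,38,0
F,meta,boronic,8.15,38,0
F,para,boronic,8.66,37,0
F,para,boronic,8.77,38,0
F,para,boronic,8.71,38,0
F,para,boronic,8.6,40,0
F,para,boronic,9.1,41,0
F,para,boronic,9.0,39,0
Cl,ortho,benzoic,2.94,42,0
Cl,ortho,benzoic,3.01,28,0
Cl,meta,benzoic,3.82,42,0
Cl,meta,benzoic,3.70,28,0
Cl,meta,benzoic,3.84,25,0
Cl,para,benzoic,3.98,42,0
Cl,para,benzoic,4.00,28,0
Cl,para,benzoic,4.00,25,0
Cl,para,boronic,8.3,29,0
Br,ortho,benzoic,2.85,42,0
Br,ortho,benzoic,2.81,28,0
Br,meta,benzoic,3.81,42,0
Br,meta,benzoic,3.78,28,0
Br,para,benzoic,4.00,25,0
Br,para,benzoic,3.93,28,0
Br,para,benzoic,3.99,25,0
Br,para,boronic,8.8,40,0
I,ortho,benzoic,2.84,28,0
I,meta,benzoic,3.79,28,0
I,meta,benzoic,3.88,25,0
I,para,benzoic,3.98,28,0
I,para,benzoic,4.00,25,0
I,ortho,boronic,8.9,43,0
CN,ortho,benzoic,3.14,44,0
CN,meta,benzoic,3.59,25,0
CN,para,benzoic,3.5,25,0
CN,meta,boronic,7.5,39,0
CN,para,boronic,7.7,39,0
CH3,ortho,benzoic,3.81,28,0
CH3,meta,benzoic,4.24,28,0
CH3,meta,benzoic,4.27,25,0
CH3,para,benzoic,4.36,28,0
CH3,para,benzoic,4.35,25,0
CH3,ortho,boronic,9.7,29,0
CH3,meta,boronic,9.0,29,0
CH3,meta,boronic,9.00,33,0
CH3,meta,boronic,8.74,34,0
CH3,para,boronic,9.3,29,0
CH3,para,boronic,9.26,33,0
CH3,para,boronic,8.95,34,0
OCH3,ortho,benzoic,4.02,28,0
OCH3,meta,benzoic,3.92,28,0
OCH3,meta,benzoic,4.12,25,0
OCH3,para,benzoic,4.41,28,0
OCH3,para,benzoic,4.49,25,0
OCH3,ortho,boronic,9.0,45,0
OCH3,ortho,boronic,9.0,40,0
OCH3,ortho,boronic,9.0,39,0
OCH3,ortho,boronic,9.7,29,0
OCH3,meta,boronic,8.7,45,0
OCH3,meta,boronic,8.5,40,0
OCH3,meta,boronic,8.7,41,0
OCH3,meta,boronic,8.4,39,0
OCH3,para,boronic,9.3,45,0
OCH3,para,boronic,9.3,29,0
OCH3,para,boronic,9.32,46,0
CHO,ortho,benzoic,4.56,47,0
CHO,ortho,benzoic,4.5,49,0
CHO,meta,benzoic,3.77,48,0
CHO,ortho,boronic,7.3,45,0
CHO,ortho,boronic,7.31,46,0
CHO,meta,boronic,7.5,45,0
CHO,meta,boronic,7.8,40,0
CHO,meta,boronic,7.80,46,0
CHO,para,boronic,7.7,45,0
CHO,para,boronic,7.6,40,0
CHO,para,boronic,7.80,46,0
COCH3,meta,benzoic,3.86,25,0
COCH3,para,benzoic,3.74,25,0
COCH3,meta,boronic,8.0,45,0
COCH3,meta,boronic,8.0,40,0
COCH3,para,boronic,7.7,45,0
COCH3,para,boronic,7.7,40,0
NO2,ortho,benzoic,2.17,42,0
NO2,ortho,benzoic,2.14,28,0
NO2,meta,benzoic,3.45,42,0
NO2,meta,benzoic,3.50,25,0
NO2,para,benzoic,3.44,42,0
NO2,para,benzoic,3.40,25,0
NO2,ortho,boronic,8.5,46,1
NO2,meta,boronic,7.1,40,0
NO2,meta,boronic,7.3,46,0
NO2,para,boronic,7.4,39,0
NO2,para,boronic,7.15,46,0
CF3,ortho,benzoic,2.73,50,0
CF3,meta,benzoic,3.75,25,0
CF3,meta,benzoic,3.90,50,0
CF3,para,benzoic,3.77,51,0
CF3,para,benzoic,3.77,50,0
CF3,ortho,boronic,9.58,52,0
CF3,ortho,boronic,9.45,52,0
CF3,ortho,boronic,8.5,39,0
CF3,meta,boronic,7.88,52,0
CF3,meta,boronic,7.85,52,0
CF3,meta,boronic,7.87,37,0
CF3,meta,boronic,7.9,39,0
CF3,para,boronic,7.39,37,0
CF3,para,boronic,8.1,39,0
CF3,para,boronic,7.82,52,0
CF3,para,boronic,7.90,52,0
OCF3,ortho,boronic,9.53,53,0
OCF3,ortho,boronic,9.49,53,0
OCF3,meta,boronic,7.79,53,0
OCF3,meta,boronic,7.96,53,0
OCF3,para,boronic,8.11,53,0
OCF3,para,boronic,8.03,53,0
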