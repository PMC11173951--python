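substituent,position,pka_s,u_s,pka_p1,u_p1,pka_p2,u_p2,sigma
F,ortho,7.89,0.01,7.85,0.07,,,
F,meta,8.09,0.01,8.15,0.11,,,0.34
F,para,8.77,0.01,8.71,0.10,,,0.06
Cl,ortho,8.08,0.01,8.07,0.02,7.96,0.02,
Cl,meta,7.93,0.02,7.95,0.03,7.81,0.01,0.37
Cl,para,8.67,0.04,8.24,0.04,8.17,0.02,0.23
Br,ortho,8.09,0.03,8.18,0.03,8.04,0.03,
Br,meta,7.90,0.04,7.94,0.03,7.77,0.01,0.39
Br,para,8.19,0.01,8.22,0.05,8.19,0.03,0.23
I,ortho,8.63,0.03,8.51,0.04,7.92,0.02,
I,meta,8.13,0.05,8.01,0.03,7.79,0.03,0.35
I,para,8.56,0.01,8.42,0.05,8.06,0.01,0.18
CN,ortho,7.01,0.10,6.89,0.08,,,
CN,meta,7.50,0.02,7.40,0.04,,,0.56
CN,para,7.32,0.04,7.24,0.04,,,0.66
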