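substituent,pka_water_spectro,pka_water_pot,pka_water_dioxane
2F,7.89,7.85,10.14
3F,8.09,8.15,10.46
4F,8.77,8.71,10.97
"2,3F",6.99,6.93,9.51
"2,4F",7.75,7.73,10.02
"2,5F",7.06,7.01,9.34
"2,6F",7.37,7.41,9.15
"3,4F",7.74,,10.34
"3,5F",7.60,7.52,9.78
"2,3,4F",6.97,7.01,9.06
"2,3,5F",6.34,6.38,8.47
"2,3,6F",5.60,,8.66
"2,4,5F",7.06,6.98,9.00
"2,4,6F",7.10,,9.03
"3,4,5F",7.34,7.32,9.44
"2,3,4,5F",6.23,6.17,8.91
"2,3,4,6F",6.17,6.19,8.39
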