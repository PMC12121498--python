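conformer,MP2_aVTZ,CCSD_T,PES,PES_wt
tG+g-,0.0,0.0,0.0,0.0
g+G+g-,149,113,69,79
g-G+g-,330,305,290,292
tTt,912,876,905,912
g+Tg-,979,908,1015,1018
tTg+,971,919,904,894
g+Tg+,1046,968,972,990
tG+t,1084,1093,1115,1111
tG+g+,1249,1210,1219,1215
cCt,2298,2324,2252,2261
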