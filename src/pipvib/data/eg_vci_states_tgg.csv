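band_mode,harm_freq,ci_freq,c1,c2,c3,label1,label2,label3
10,1135,1119,0.9957,,,nu10,,
11,1207,1167,-0.9889,0.0581,0.0455,nu11,nu12,nu14
12,1277,1246,0.9774,0.1745,0.0632,nu12,nu13,nu11
13,1314,1268,-0.9633,0.1771,0.1318,nu13,nu12,nu15
14,1390,1340,0.9344,0.3043,0.1418,nu14,nu15,nu13
15,1429,1387,-0.9354,0.3206,-0.0952,nu15,nu14,nu13
16,1465,1429,-0.9913,-0.0475,0.0418,nu16,nu18,nu15
17,1519,1472,0.9552,-0.2789,-0.0396,nu17,nu18,nu15
18,1525,1478,0.9549,0.2799,-0.0395,nu18,nu17,nu16
19,3056,2798,0.8310,-0.3908,0.2718,nu15+nu16,nu19,2nu16
19,3056,2918,0.5991,0.4551,0.3765,nu19,2nu18,2nu16
19,3056,2972,0.6764,-0.3948,0.3448,nu21,2nu18,nu19
19,3056,2981,-0.5441,0.5289,-0.4209,nu17+nu18,nu21,nu19
20,3064,2836,-0.8092,0.3438,-0.2593,2nu16,nu15+nu15,nu20
20,3064,2906,-0.8184,0.2904,-0.2245,nu16+nu17,nu20,nu17+nu18
20,3064,2915,0.5181,0.4893,0.4766,nu16+nu17,2nu17,nu20
20,3064,2961,0.5192,0.4968,0.4057,nu20,nu17+nu18,2nu18
21,3118,2972,0.6764,-0.3948,0.3448,nu21,2nu18,nu19
21,3118,2981,-0.5441,0.5289,-0.4209,nu17+nu18,nu21,nu19
22,3148,3012,-0.8881,-0.1973,0.1762,nu22,2nu17,nu17+nu18
23,3831,3629,-0.9645,-0.0877,-0.0796,nu23,nu11+2nu13,2nu10+nu15
24,3871,3681,0.9600,-0.1649,0.0869,nu24,nu11+2nu13,nu23
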