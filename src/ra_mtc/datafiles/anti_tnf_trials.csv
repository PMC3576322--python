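trial_id,drug,n,mtx,haq_mean,haq_sd,acr20,acr50,acr70,haq_baseline
Weinblatt-a,P,62,1,0.27,0.6,9,5,3,1.64
Weinblatt-a,Ada,69,1,0.54,0.6,33,22,7,1.52
Weinblatt-a,Ada,67,1,0.62,0.6,45,37,18,1.55
Weinblatt-a,Ada,73,1,0.59,0.5,48,31,14,1.55
Keystone-a,P,200,1,0.24,0.5,59,19,5,1.45
Keystone-a,Ada,207,1,0.56,0.5,131,81,43,1.44
Keystone-a,Ada,212,1,0.60,0.5,129,87,37,1.48
VanDePutte,P,110,0,0.07,0.5,21,9,2,1.88
VanDePutte,Ada,112,0,0.39,0.6,44,23,11,1.88
VanDePutte,Ada,106,0,0.29,0.6,38,20,9,1.88
VanDePutte,Ada,103,0,0.49,0.5,55,36,19,1.84
VanDePutte,Ada,113,0,0.38,0.6,52,25,14,1.83
Miyasaka,P,87,0,-0.1,0.6,12,5,1,1.39
Miyasaka,Ada,87,0,0.2,0.5,25,14,9,1.57
Miyasaka,Ada,91,0,0.2,0.6,40,22,11,1.64
Miyasaka,Ada,87,0,0.4,0.6,44,28,13,1.77
Kim,P,63,1,0.2,0.5,23,9,5,1.3
Kim,Ada,65,1,0.5,0.6,40,28,14,1.4
Maini,P,88,1,0.3,0.5,18,7,0,1.8
Maini,Inf,86,1,0.3,0.5,45,22,7,1.8
Maini,Inf,86,1,0.5,0.5,47,25,9,1.8
Maini,Inf,87,1,0.5,0.6,51,26,15,1.8
Maini,Inf,81,1,0.4,0.5,49,21,9,1.5
Westhoven,P,363,1,-,-,87,33,16,1.5
Westhoven,Inf,360,1,-,-,199,110,48,1.5
Westhoven,Inf,361,1,-,-,205,119,54,1.5
Zhang,P,86,1,0.45,-,42,22,12,1.6
Zhang,Inf,87,1,0.76,-,66,38,20,1.6
Schiff,P,110,1,-,-,49,22,10,1.8
Schiff,Inf,165,1,-,-,98,61,40,1.7
Moreland,P,80,0,0.03,-,9,4,1,1.7
Moreland,Eta,76,0,0.58,-,39,18,7,1.7
Moreland,Eta,78,0,0.62,-,46,31,12,1.6
Weinblatt-b,P,30,1,0.4,-,8,1,0,1.5
Weinblatt-b,Eta,59,1,0.7,-,42,23,9,1.5
Keystone-b,P,133,1,0.13,0.4,37,18,7,1.25
Keystone-b,Gol,133,0,0.13,0.7,47,26,15,1.38
Keystone-b,Gol,89,1,0.38,0.5,53,33,18,1.38
Keystone-b,Gol,89,1,0.5,0.5,53,29,16,1.38
Kay,P,35,1,-,-,13,2,0,1.3
Kay,Gol,35,1,-,-,21,13,3,1.7
Kay,Gol,34,1,-,-,19,10,6,1.8
Keystone-c,P,199,1,0.18,-,27,15,6,1.7
Keystone-c,Cert,393,1,0.60,-,231,146,84,1.7
Keystone-c,Cert,390,1,0.63,-,237,156,79,1.7
Smolen,P,127,1,0.14,0.5,11,4,1,1.6
Smolen,Cert,246,1,0.5,0.5,141,80,39,1.6
Smolen,Cert,246,1,0.5,0.5,142,81,26,1.6
Fleischmann,P,109,0,-0.07,0.4,10,4,0,1.6
Fleischmann,Cert,111,0,0.39,0.7,51,25,9,1.4
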