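trial_id,drug,n,haq20,haq50,acrcont_mean,acrcont_sd
Weinblatt-a,P,62,30,12,0.08,0.22
Weinblatt-a,Ada,69,45,24,0.35,0.20
Weinblatt-a,Ada,67,47,26,0.46,0.22
Weinblatt-a,Ada,73,52,26,0.42,0.21
Keystone-a,P,200,95,32,0.13,0.22
Keystone-a,Ada,212,141,81,0.42,0.21
Keystone-a,Ada,207,154,82,0.41,0.21
VanDePutte,P,110,29,4,0.09,0.20
VanDePutte,Ada,112,47,16,0.31,0.19
VanDePutte,Ada,106,60,19,0.30,0.19
VanDePutte,Ada,103,57,20,0.38,0.22
VanDePutte,Ada,113,60,21,0.33,0.20
Miyasaka,P,87,23,8,0.07,0.17
Miyasaka,Ada,87,37,10,0.28,0.19
Miyasaka,Ada,91,39,16,0.33,0.20
Miyasaka,Ada,87,48,18,0.37,0.21
Kim,P,63,28,10,0.18,0.27
Kim,Ada,65,43,24,0.42,0.22
Maini,P,88,40,9,0.09,0.19
Maini,Inf,86,40,12,0.35,0.19
Maini,Inf,86,54,19,0.36,0.20
Maini,Inf,87,52,23,0.38,0.21
Maini,Inf,81,48,20,0.37,0.19
Westhoven,P,363,-,-,0.12,0.23
Westhoven,Inf,360,-,-,0.37,0.20
Westhoven,Inf,361,-,-,0.38,0.21
Zhang,P,86,52,28,0.27,0.31
Zhang,Inf,87,61,39,0.46,0.20
Schiff,P,110,-,-,0.22,0.29
Schiff,Inf,165,-,-,0.41,0.22
Moreland,P,80,25,8,0.06,0.16
Moreland,Eta,76,47,26,0.34,0.19
Moreland,Eta,78,53,31,0.40,0.21
Weinblatt-b,P,30,16,8,0.10,0.17
Weinblatt-b,Eta,59,45,29,0.43,0.19
Keystone-b,P,133,49,13,0.14,0.25
Keystone-b,Gol,133,56,29,0.30,0.20
Keystone-b,Gol,89,51,24,0.40,0.22
Keystone-b,Gol,89,60,31,0.39,0.21
Kay,P,35,-,-,0.14,0.20
Kay,Gol,35,-,-,0.39,0.20
Kay,Gol,34,-,-,0.38,0.21
Keystone-c,P,199,83,35,0.07,0.20
Keystone-c,Cert,393,263,146,0.40,0.22
Keystone-c,Cert,390,249,137,0.41,0.22
Smolen,P,127,46,10,0.04,0.14
Smolen,Cert,246,163,66,0.38,0.21
Smolen,Cert,246,155,67,0.38,0.20
Fleischmann,P,109,19,2,0.04,0.14
Fleischmann,Cert,111,60,34,0.33,0.19
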