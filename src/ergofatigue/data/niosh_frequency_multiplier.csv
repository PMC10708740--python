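lifts_per_min,d1_vlow,d1_vhigh,d2_vlow,d2_vhigh,d8_vlow,d8_vhigh
0.2,1.00,1.00,.95,.95,.85,.85
0.5,.97,.97,.92,.92,.81,.81
1,.94,.94,.88,.88,.75,.75
2,.91,.91,.84,.84,.65,.65
3,.88,.88,.79,.79,.55,.55
4,.84,.84,.72,.72,.45,.45
5,.80,.80,.60,.60,.35,.35
6,.75,.75,.50,.50,.27,.27
7,.70,.70,.42,.42,.22,.22
8,.60,.60,.35,.35,.18,.18
9,.52,.52,.30,.30,.00,.15
10,.45,.45,.26,.26,.00,.13
11,.41,.41,.00,.23,.00,.00
12,.37,.37,.00,.21,.00,.00
13,.00,.34,.00,.00,.00,.00
14,.00,.31,.00,.00,.00,.00
15,.00,.28,.00,.00,.00,.00
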