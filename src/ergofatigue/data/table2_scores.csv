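height_cm,weight_kg,replicate,niosh_li,owas_category,rula_grand
15,8,1,0.46,1,6
15,8,2,0.59,1,6
15,8,3,0.43,1,6
15,14,1,1.1,3,6
15,14,2,1.28,3,6
15,14,3,0.93,3,7
15,20,1,1.88,3,5
15,20,2,2.01,3,6
15,20,3,2.51,4,7
45,8,1,0.59,1,3
45,8,2,0.42,1,4
45,8,3,0.51,1,4
45,14,1,0.9,2,4
45,14,2,0.95,3,4
45,14,3,0.87,3,4
45,20,1,1.83,3,4
45,20,2,1.94,3,4
45,20,3,2.18,3,5
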