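height_cm,weight_kg,replicate,fatigue_score
15,8,1,0.010766997
15,8,2,0.011034003
15,8,3,0.01072171
15,14,1,0.019983377
15,14,2,0.020297028
15,14,3,0.020373405
15,20,1,0.020962028
15,20,2,0.022100687
15,20,3,0.027797152
45,8,1,0.008193415
45,8,2,0.008682337
45,8,3,0.008965525
45,14,1,0.014098114
45,14,2,0.01775242
45,14,3,0.017608327
45,20,1,0.020047302
45,20,2,0.020818436
45,20,3,0.020569058
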