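height_cm,weight_kg,replicate,rso2_diff_pct
15,8,1,-4.26
15,8,2,-4.12
15,8,3,-4.02
15,14,1,-9.92
15,14,2,-9.92
15,14,3,-9.9
15,20,1,-15.11
15,20,2,-16.25
15,20,3,-18.46
45,8,1,-2.57
45,8,2,-2.34
45,8,3,-2.63
45,14,1,-6.33
45,14,2,-6.42
45,14,3,-7.62
45,20,1,-12.89
45,20,2,-13.04
45,20,3,-15.58
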