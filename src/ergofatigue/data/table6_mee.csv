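height_cm,weight_kg,replicate,mee_kcal
15,8,1,1267.80
15,8,2,1295.80
15,8,3,1349.33
15,14,1,1575.37
15,14,2,1573.48
15,14,3,1747.11
15,20,1,1886.35
15,20,2,1870.81
15,20,3,1814.05
45,8,1,1215.47
45,8,2,1235.22
45,8,3,1190.07
45,14,1,1519.52
45,14,2,1537.95
45,14,3,1535.00
45,20,1,1867.15
45,20,2,1901.10
45,20,3,1691.50
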