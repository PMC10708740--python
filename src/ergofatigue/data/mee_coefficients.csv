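posture,k_kcal_per_min_kg
lifting,0.100
walking_with_load,0.080
walking,0.055
deep_bend_standing,0.035
bent_standing,0.030
bending,0.040
standing,0.022
sitting,0.020
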