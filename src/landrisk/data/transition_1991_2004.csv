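,farmland,forest,built_up,water,aquaculture,other
farmland,70348.32,425.07,5256.45,89.01,11248.29,491.13
forest,141.66,7992.18,400.86,1.62,120.96,317.34
built_up,684.00,67.50,11769.93,58.05,336.15,731.25
water,152.19,96.66,178.65,32744.34,1412.46,248.67
aquaculture,158.49,11.97,713.52,90.45,6344.64,57.87
other,119.70,600.57,551.43,6.93,408.78,7053.48
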