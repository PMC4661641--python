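,farmland,forest,built_up,water,aquaculture,other
farmland,52086.15,4495.41,7686.72,321.12,4587.84,2427.12
forest,1307.52,6518.97,459.36,17.10,78.75,812.25
built_up,2025.18,635.40,15162.48,51.21,430.92,565.65
water,965.34,112.59,1102.41,27523.62,2513.07,773.37
aquaculture,3625.65,117.72,1809.45,707.49,13295.52,315.45
other,1684.71,2655.90,1282.59,105.48,709.47,2461.59
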