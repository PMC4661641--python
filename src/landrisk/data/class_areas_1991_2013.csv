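year,farmland,forest,built_up,water,aquaculture,other
1991,87858.27,8974.62,13646.88,34832.97,7376.94,8740.89
2004,71604.36,9193.95,18870.84,32990.40,19871.28,8899.74
2013,61694.55,14535.99,27503.01,28726.02,21615.57,7355.43
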