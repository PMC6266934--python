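# Nine spaced seeds of weight 22 and span 31 used in the benchmark
# experiments, three per design family.
# maximizing the hit probability
1111011101110010111001011011111
1111101011100101101110011011111
1111101001110101101100111011111
# minimizing the overlap complexity
1111010111010011001110111110111
1110111011101111010010110011111
1111101001011100111110101101111
# maximizing the sensitivity
1111011110011010111110101011011
1110101011101100110100111111111
1111110101101011100111011001111
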