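MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25000 C 0.25000 G 0.25000 T 0.25000

MOTIF PRE_full
letter-probability matrix: alength= 4 w= 15 nsites= 20 E= 0
 0.500000 0.000000 0.500000 0.000000
 0.000000 0.000000 1.000000 0.000000
 0.250000 0.250000 0.250000 0.250000
 1.000000 0.000000 0.000000 0.000000
 0.000000 1.000000 0.000000 0.000000
 1.000000 0.000000 0.000000 0.000000
 0.250000 0.250000 0.250000 0.250000
 0.250000 0.250000 0.250000 0.250000
 0.250000 0.250000 0.250000 0.250000
 0.000000 0.000000 0.000000 1.000000
 0.000000 0.000000 1.000000 0.000000
 0.000000 0.000000 0.000000 1.000000
 0.250000 0.250000 0.250000 0.250000
 0.000000 1.000000 0.000000 0.000000
 0.000000 0.500000 0.000000 0.500000

MOTIF PRE_core
letter-probability matrix: alength= 4 w= 10 nsites= 20 E= 0
 0.000000 1.000000 0.000000 0.000000
 0.500000 0.000000 0.000000 0.500000
 0.250000 0.250000 0.250000 0.250000
 0.250000 0.250000 0.250000 0.250000
 0.250000 0.250000 0.250000 0.250000
 0.000000 0.000000 0.000000 1.000000
 0.000000 0.000000 1.000000 0.000000
 0.000000 0.000000 0.000000 1.000000
 0.250000 0.250000 0.250000 0.250000
 0.000000 1.000000 0.000000 0.000000

MOTIF FOXA1
letter-probability matrix: alength= 4 w= 9 nsites= 20 E= 0
 0.000000 0.000000 0.000000 1.000000
 0.500000 0.000000 0.500000 0.000000
 0.000000 0.000000 0.000000 1.000000
 0.000000 0.000000 0.000000 1.000000
 0.000000 0.000000 0.500000 0.500000
 0.500000 0.000000 0.500000 0.000000
 0.000000 0.500000 0.000000 0.500000
 0.000000 0.000000 0.000000 1.000000
 0.000000 0.500000 0.000000 0.500000

MOTIF NF1
letter-probability matrix: alength= 4 w= 15 nsites= 20 E= 0
 0.000000 0.000000 0.000000 1.000000
 0.000000 0.000000 0.000000 1.000000
 0.000000 0.000000 1.000000 0.000000
 0.000000 0.000000 1.000000 0.000000
 0.000000 1.000000 0.000000 0.000000
 0.250000 0.250000 0.250000 0.250000
 0.250000 0.250000 0.250000 0.250000
 0.250000 0.250000 0.250000 0.250000
 0.250000 0.250000 0.250000 0.250000
 0.250000 0.250000 0.250000 0.250000
 0.000000 0.000000 1.000000 0.000000
 0.000000 1.000000 0.000000 0.000000
 0.000000 1.000000 0.000000 0.000000
 1.000000 0.000000 0.000000 0.000000
 1.000000 0.000000 0.000000 0.000000

MOTIF AP1
letter-probability matrix: alength= 4 w= 7 nsites= 20 E= 0
 0.000000 0.000000 0.000000 1.000000
 0.000000 0.000000 1.000000 0.000000
 1.000000 0.000000 0.000000 0.000000
 0.000000 0.500000 0.500000 0.000000
 0.000000 0.000000 0.000000 1.000000
 0.000000 1.000000 0.000000 0.000000
 1.000000 0.000000 0.000000 0.000000

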