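
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M    -1  -2  -3  -4  -2  -1  -3  -3  -2   1   2  -2   8   0  -3  -2  -1  -2  -1   1
    2 K    -1   2   0  -1  -4   1   1  -2  -1  -3  -3   5  -2  -4  -1   0  -1  -4  -2  -3
    3 T     0  -1   0  -1  -1  -1  -1  -2  -2  -1  -2  -1  -1  -2  -1   1   6  -3  -2   0
    4 A     4  -2  -2  -2  -1  -1  -1   0  -2  -2  -2  -1  -1  -3  -1   1   0  -3  -2   0
    5 Y    -2  -2  -2  -3  -3  -2  -2  -3   2  -2  -1  -2  -1   3  -3  -2  -2   2   8  -1
    6 I    -2  -3  -4  -4  -1  -3  -4  -4  -4   5   2  -3   1   0  -3  -3  -1  -3  -2   3
    7 A     5  -2  -2  -2  -1  -1  -1   0  -2  -2  -2  -1  -1  -3  -1   1   0  -3  -2   0
    8 K    -1   2   0  -1  -4   1   1  -2  -1  -3  -3   6  -2  -4  -1   0  -1  -4  -2  -3
    9 Q    -1   1   0   0  -3   6   2  -2   0  -3  -2   1   0  -4  -2   0  -1  -2  -2  -3
   10 R    -2   7  -1  -2  -4   1   0  -3  -1  -3  -3   2  -2  -3  -2  -1  -1  -3  -2  -3

                      K         Lambda
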