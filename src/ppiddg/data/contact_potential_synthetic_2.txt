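H SYNCP2
D Synthetic substitute contact potential 2: formal charge-pair score
R synthetic stand-in table shipped with ppiddg; replace via configuration with a real AAindex entry
M rows = ARNDCQEGHILKMFPSTWYV, cols = ARNDCQEGHILKMFPSTWYV
   0.00
   0.00   1.00
   0.00   0.00   0.00
  -0.00  -1.00  -0.00   1.00
   0.00   0.00   0.00  -0.00   0.00
   0.00   0.00   0.00  -0.00   0.00   0.00
  -0.00  -1.00  -0.00   1.00  -0.00  -0.00   1.00
   0.00   0.00   0.00  -0.00   0.00   0.00  -0.00   0.00
   0.00   0.50   0.00  -0.50   0.00   0.00  -0.50   0.00   0.25
   0.00   0.00   0.00  -0.00   0.00   0.00  -0.00   0.00   0.00   0.00
   0.00   0.00   0.00  -0.00   0.00   0.00  -0.00   0.00   0.00   0.00   0.00
   0.00   1.00   0.00  -1.00   0.00   0.00  -1.00   0.00   0.50   0.00   0.00   1.00
   0.00   0.00   0.00  -0.00   0.00   0.00  -0.00   0.00   0.00   0.00   0.00   0.00   0.00
   0.00   0.00   0.00  -0.00   0.00   0.00  -0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
   0.00   0.00   0.00  -0.00   0.00   0.00  -0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
   0.00   0.00   0.00  -0.00   0.00   0.00  -0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
   0.00   0.00   0.00  -0.00   0.00   0.00  -0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
   0.00   0.00   0.00  -0.00   0.00   0.00  -0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
   0.00   0.00   0.00  -0.00   0.00   0.00  -0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
   0.00   0.00   0.00  -0.00   0.00   0.00  -0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
//
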