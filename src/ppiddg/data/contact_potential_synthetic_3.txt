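H SYNCP3
D Synthetic substitute contact potential 3: side-chain volume mismatch (|dV|/100 A^3)
R synthetic stand-in table shipped with ppiddg; replace via configuration with a real AAindex entry
M rows = ARNDCQEGHILKMFPSTWYV, cols = ARNDCQEGHILKMFPSTWYV
   0.00
   0.85   0.00
   0.26   0.59   0.00
   0.23   0.62   0.03   0.00
   0.20   0.65   0.06   0.03   0.00
   0.55   0.30   0.30   0.33   0.35   0.00
   0.50   0.35   0.24   0.27   0.30   0.05   0.00
   0.28   1.13   0.54   0.51   0.48   0.84   0.78   0.00
   0.65   0.20   0.39   0.42   0.45   0.09   0.15   0.93   0.00
   0.78   0.07   0.53   0.56   0.58   0.23   0.28   1.07   0.14   0.00
   0.78   0.07   0.53   0.56   0.58   0.23   0.28   1.07   0.14   0.00   0.00
   0.80   0.05   0.55   0.57   0.60   0.25   0.30   1.08   0.15   0.02   0.02   0.00
   0.74   0.10   0.49   0.52   0.54   0.19   0.24   1.03   0.10   0.04   0.04   0.06   0.00
   1.01   0.17   0.76   0.79   0.81   0.46   0.52   1.30   0.37   0.23   0.23   0.21   0.27   0.00
   0.24   0.61   0.01   0.02   0.04   0.31   0.26   0.53   0.40   0.54   0.54   0.56   0.50   0.77   0.00
   0.00   0.84   0.25   0.22   0.20   0.55   0.49   0.29   0.64   0.78   0.78   0.80   0.74   1.01   0.24   0.00
   0.28   0.57   0.02   0.05   0.08   0.28   0.22   0.56   0.37   0.51   0.51   0.53   0.47   0.74   0.03   0.27   0.00
   1.39   0.54   1.14   1.17   1.19   0.84   0.89   1.68   0.75   0.61   0.61   0.59   0.65   0.38   1.15   1.39   1.12   0.00
   1.05   0.20   0.80   0.82   0.85   0.50   0.55   1.33   0.40   0.27   0.27   0.25   0.31   0.04   0.81   1.05   0.78   0.34   0.00
   0.51   0.33   0.26   0.29   0.32   0.04   0.02   0.80   0.13   0.27   0.27   0.29   0.23   0.50   0.27   0.51   0.24   0.88   0.54   0.00
//
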