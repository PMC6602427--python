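H SYNCP1
D Synthetic substitute contact potential 1: hydrophobic-pairing score (product of Kyte-Doolittle hydropathies, negated, /10)
R synthetic stand-in table shipped with ppiddg; replace via configuration with a real AAindex entry
M rows = ARNDCQEGHILKMFPSTWYV, cols = ARNDCQEGHILKMFPSTWYV
  -0.32
   0.81  -2.02
   0.63  -1.57  -1.23
   0.63  -1.57  -1.23  -1.23
  -0.45   1.12   0.88   0.88  -0.62
   0.63  -1.57  -1.23  -1.23   0.88  -1.23
   0.63  -1.57  -1.23  -1.23   0.88  -1.23  -1.23
   0.07  -0.18  -0.14  -0.14   0.10  -0.14  -0.14  -0.02
   0.58  -1.44  -1.12  -1.12   0.80  -1.12  -1.12  -0.13  -1.02
  -0.81   2.02   1.57   1.57  -1.12   1.57   1.57   0.18   1.44  -2.02
  -0.68   1.71   1.33   1.33  -0.95   1.33   1.33   0.15   1.22  -1.71  -1.44
   0.70  -1.76  -1.36  -1.36   0.97  -1.36  -1.36  -0.16  -1.25   1.76   1.48  -1.52
  -0.34   0.85   0.66   0.66  -0.47   0.66   0.66   0.08   0.61  -0.85  -0.72   0.74  -0.36
  -0.50   1.26   0.98   0.98  -0.70   0.98   0.98   0.11   0.90  -1.26  -1.06   1.09  -0.53  -0.78
   0.29  -0.72  -0.56  -0.56   0.40  -0.56  -0.56  -0.06  -0.51   0.72   0.61  -0.62   0.30   0.45  -0.26
   0.14  -0.36  -0.28  -0.28   0.20  -0.28  -0.28  -0.03  -0.26   0.36   0.30  -0.31   0.15   0.22  -0.13  -0.06
   0.13  -0.32  -0.24  -0.24   0.17  -0.24  -0.24  -0.03  -0.22   0.32   0.27  -0.27   0.13   0.20  -0.11  -0.06  -0.05
   0.16  -0.40  -0.32  -0.32   0.23  -0.32  -0.32  -0.04  -0.29   0.40   0.34  -0.35   0.17   0.25  -0.14  -0.07  -0.06  -0.08
   0.23  -0.59  -0.45  -0.45   0.33  -0.45  -0.45  -0.05  -0.42   0.59   0.49  -0.51   0.25   0.36  -0.21  -0.10  -0.09  -0.12  -0.17
  -0.76   1.89   1.47   1.47  -1.05   1.47   1.47   0.17   1.34  -1.89  -1.60   1.64  -0.80  -1.18   0.67   0.34   0.29   0.38   0.55  -1.76
//
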