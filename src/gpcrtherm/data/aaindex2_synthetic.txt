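* synthetic reconstructions of amino-acid pair matrices, version 1
* values derived in-package (see module docs); not the published entries
H BENS940104
D Genetic-code interconvertibility (synthetic reconstruction): max base matches between codon sets
M rows = ARNDCQEGHILKMFPSTWYV, cols = ARNDCQEGHILKMFPSTWYV
     3.00
     1.00    3.00
     1.00    1.00    3.00
     2.00    1.00    2.00    3.00
     1.00    2.00    1.00    1.00    3.00
     1.00    2.00    1.00    1.00    0.00    3.00
     2.00    1.00    1.00    2.00    0.00    2.00    3.00
     2.00    2.00    1.00    2.00    2.00    1.00    2.00    3.00
     1.00    2.00    2.00    2.00    1.00    2.00    1.00    1.00    3.00
     1.00    2.00    2.00    1.00    1.00    1.00    1.00    1.00    1.00    3.00
     1.00    2.00    1.00    1.00    1.00    2.00    1.00    1.00    2.00    2.00    3.00
     1.00    2.00    2.00    1.00    0.00    2.00    2.00    1.00    1.00    2.00    1.00    3.00
     1.00    2.00    1.00    0.00    0.00    1.00    1.00    1.00    0.00    2.00    2.00    2.00    3.00
     1.00    1.00    1.00    1.00    2.00    0.00    0.00    1.00    1.00    2.00    2.00    0.00    1.00    3.00
     2.00    2.00    1.00    1.00    1.00    2.00    1.00    1.00    2.00    1.00    2.00    1.00    1.00    1.00    3.00
     2.00    2.00    2.00    1.00    2.00    1.00    1.00    2.00    1.00    2.00    2.00    1.00    1.00    2.00    2.00    3.00
     2.00    2.00    2.00    1.00    1.00    1.00    1.00    1.00    1.00    2.00    1.00    2.00    2.00    1.00    2.00    2.00    3.00
     1.00    2.00    0.00    0.00    2.00    1.00    1.00    2.00    0.00    0.00    2.00    1.00    1.00    1.00    1.00    2.00    1.00    3.00
     1.00    1.00    2.00    2.00    2.00    1.00    1.00    1.00    2.00    1.00    1.00    1.00    0.00    2.00    1.00    2.00    1.00    1.00    3.00
     2.00    1.00    1.00    2.00    1.00    1.00    2.00    2.00    1.00    2.00    2.00    1.00    2.00    2.00    1.00    1.00    1.00    1.00    1.00    3.00
//
H LUTR910108
D Alpha-helix substitution compatibility (synthetic reconstruction from helix propensities)
M rows = ARNDCQEGHILKMFPSTWYV, cols = ARNDCQEGHILKMFPSTWYV
    -0.00
    -0.32   -0.21
    -0.98   -0.87   -0.65
    -1.03   -0.93   -0.71   -0.69
    -1.02   -0.92   -0.70   -0.69   -0.68
    -0.58   -0.48   -0.78   -0.84   -0.83   -0.39
    -0.60   -0.49   -0.78   -0.83   -0.82   -0.41   -0.40
    -1.50   -1.40   -1.17   -1.16   -1.16   -1.31   -1.30   -1.00
    -0.92   -0.81   -0.67   -0.73   -0.72   -0.72   -0.71   -1.19   -0.61
    -0.61   -0.51   -0.77   -0.83   -0.82   -0.42   -0.41   -1.29   -0.71   -0.41
    -0.32   -0.21   -0.87   -0.93   -0.92   -0.48   -0.49   -1.40   -0.81   -0.51   -0.21
    -0.39   -0.29   -0.84   -0.90   -0.89   -0.46   -0.47   -1.37   -0.78   -0.48   -0.29   -0.26
    -0.36   -0.26   -0.85   -0.91   -0.90   -0.47   -0.48   -1.38   -0.79   -0.49   -0.26   -0.27   -0.24
    -0.81   -0.71   -0.70   -0.76   -0.75   -0.61   -0.61   -1.23   -0.64   -0.60   -0.71   -0.68   -0.69   -0.54
    -4.74   -4.63   -4.42   -4.40   -4.40   -4.54   -4.54   -4.24   -4.44   -4.54   -4.63   -4.61   -4.62   -4.47   -3.16
    -0.75   -0.65   -0.72   -0.78   -0.77   -0.55   -0.55   -1.25   -0.66   -0.54   -0.65   -0.62   -0.63   -0.56   -4.49   -0.50
    -0.99   -0.89   -0.67   -0.70   -0.69   -0.80   -0.79   -1.17   -0.69   -0.79   -0.89   -0.86   -0.87   -0.72   -4.41   -0.74   -0.66
    -0.73   -0.63   -0.73   -0.79   -0.78   -0.54   -0.53   -1.25   -0.67   -0.53   -0.63   -0.60   -0.61   -0.57   -4.50   -0.51   -0.74   -0.49
    -0.80   -0.69   -0.71   -0.77   -0.76   -0.60   -0.59   -1.23   -0.65   -0.59   -0.69   -0.67   -0.68   -0.55   -4.47   -0.55   -0.72   -0.55   -0.53
    -0.92   -0.81   -0.67   -0.73   -0.72   -0.72   -0.71   -1.19   -0.61   -0.71   -0.81   -0.78   -0.79   -0.64   -4.44   -0.66   -0.69   -0.67   -0.65   -0.61
//
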