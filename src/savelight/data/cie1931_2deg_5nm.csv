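wavelength_nm,xbar,ybar,zbar
400,0.014300,0.000400,0.067900
405,0.028900,0.000800,0.137650
410,0.043500,0.001200,0.207400
415,0.088950,0.002600,0.426500
420,0.134400,0.004000,0.645600
425,0.209150,0.007800,1.015600
430,0.283900,0.011600,1.385600
435,0.316100,0.017300,1.566350
440,0.348300,0.023000,1.747100
445,0.342250,0.030500,1.759600
450,0.336200,0.038000,1.772100
455,0.313500,0.049000,1.720650
460,0.290800,0.060000,1.669200
465,0.243100,0.075500,1.478400
470,0.195400,0.091000,1.287600
475,0.145500,0.115000,1.050300
480,0.095600,0.139000,0.813000
485,0.063800,0.173500,0.639100
490,0.032000,0.208000,0.465200
495,0.018450,0.265500,0.368600
500,0.004900,0.323000,0.272000
505,0.007100,0.413000,0.215100
510,0.009300,0.503000,0.158200
515,0.036300,0.606500,0.118200
520,0.063300,0.710000,0.078200
525,0.114400,0.786000,0.060200
530,0.165500,0.862000,0.042200
535,0.227950,0.908000,0.031250
540,0.290400,0.954000,0.020300
545,0.361900,0.974500,0.014500
550,0.433400,0.995000,0.008700
555,0.513950,0.995000,0.006300
560,0.594500,0.995000,0.003900
565,0.678300,0.973500,0.003000
570,0.762100,0.952000,0.002100
575,0.839200,0.911000,0.001900
580,0.916300,0.870000,0.001700
585,0.971300,0.813500,0.001400
590,1.026300,0.757000,0.001100
595,1.044250,0.694000,0.000950
600,1.062200,0.631000,0.000800
605,1.032400,0.567000,0.000550
610,1.002600,0.503000,0.000300
615,0.928500,0.442000,0.000250
620,0.854400,0.381000,0.000200
625,0.748400,0.323000,0.000125
630,0.642400,0.265000,0.000050
635,0.545150,0.220000,0.000035
640,0.447900,0.175000,0.000020
645,0.365700,0.141000,0.000010
650,0.283500,0.107000,0.000000
655,0.224200,0.084000,0.000000
660,0.164900,0.061000,0.000000
665,0.126150,0.046500,0.000000
670,0.087400,0.032000,0.000000
675,0.067100,0.024500,0.000000
680,0.046800,0.017000,0.000000
685,0.034750,0.012600,0.000000
690,0.022700,0.008200,0.000000
695,0.017050,0.006150,0.000000
700,0.011400,0.004100,0.000000
705,0.008600,0.003100,0.000000
710,0.005800,0.002100,0.000000
715,0.004350,0.001575,0.000000
720,0.002900,0.001050,0.000000
725,0.002150,0.000785,0.000000
730,0.001400,0.000520,0.000000
735,0.001050,0.000385,0.000000
740,0.000700,0.000250,0.000000
745,0.000500,0.000185,0.000000
750,0.000300,0.000120,0.000000
755,0.000235,0.000090,0.000000
760,0.000170,0.000060,0.000000
765,0.000125,0.000045,0.000000
770,0.000080,0.000030,0.000000
775,0.000060,0.000023,0.000000
780,0.000040,0.000015,0.000000
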