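wavelength_nm,d65
400,82.7500
405,87.1200
410,91.4900
415,92.4600
420,93.4300
425,90.0550
430,86.6800
435,95.7700
440,104.8600
445,110.9350
450,117.0100
455,117.4100
460,117.8100
465,116.3350
470,114.8600
475,115.3900
480,115.9200
485,112.3650
490,108.8100
495,109.0800
500,109.3500
505,108.5750
510,107.8000
515,106.2950
520,104.7900
525,106.2400
530,107.6900
535,106.0500
540,104.4100
545,104.2300
550,104.0500
555,102.0250
560,100.0000
565,98.1650
570,96.3300
575,96.0600
580,95.7900
585,92.2400
590,88.6900
595,89.3500
600,90.0100
605,89.8050
610,89.6000
615,88.6500
620,87.7000
625,85.4950
630,83.2900
635,83.4950
640,83.7000
645,81.8650
650,80.0300
655,80.1200
660,80.2100
665,81.2450
670,82.2800
675,80.2800
680,78.2800
685,74.0000
690,69.7200
695,70.6650
700,71.6100
705,72.9800
710,74.3500
715,67.9750
720,61.6000
725,65.7450
730,69.8900
735,72.4900
740,75.0900
745,69.3400
750,63.5900
755,55.0050
760,46.4200
765,56.6150
770,66.8100
775,65.0950
780,63.3800
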