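# Synthetic reconstruction of the standard compiled molar extinction spectra of
# oxygenated (eps_hbo2) and de-oxygenated (eps_hb) human hemoglobin,
# units L mol^-1 cm^-1 (per heme tetramer, molar mass 64500 g/mol).
# Values are a monotone-cubic (PCHIP) interpolation through ~50 literature
# anchor points of the widely used compilation; peak positions (HbO2 542/576 nm,
# Hb 555 nm) and isosbestic points (~500, 529, 545, 570, 584 nm) are faithful,
# absolute values approximate to ~10-20%. NOT a verbatim copy of any published
# table; suitable for simulation studies, not for clinical calibration.
wavelength_nm,eps_hbo2,eps_hb
440,32000.0,180000.0
442,34750.2,162017.2
444,39330.2,145359.5
446,45000.0,130000.0
448,55400.0,115761.9
450,62816.0,103292.0
452,62465.1,92829.6
454,61488.4,83535.3
456,60000.0,75000.0
458,54945.4,67003.1
460,48000.0,60000.0
462,42491.8,53976.1
464,37308.7,48599.9
466,33000.0,44000.0
468,29656.1,40137.6
470,27000.0,37000.0
472,24910.3,34533.5
474,23140.4,32435.4
476,21500.0,30500.0
478,19827.1,28624.1
480,18500.0,27000.0
482,17638.9,25662.0
484,16964.9,24492.1
486,16500.0,23500.0
488,16161.8,22643.4
490,16000.0,22000.0
492,16309.6,21554.6
494,17063.7,21202.7
496,18000.0,21000.0
498,19370.4,20903.6
500,20932.0,20862.0
502,22173.5,20950.9
504,23326.2,21181.6
506,24500.0,21500.0
508,25716.4,22111.0
510,27000.0,23000.0
512,28435.7,24013.3
514,29967.9,25204.4
516,31500.0,26500.0
518,32946.4,27927.0
520,34500.0,29500.0
522,36454.0,31053.8
524,38500.0,33000.0
526,40273.7,36886.2
528,42025.6,41488.3
530,44135.8,43934.9
532,46722.7,45348.4
534,49000.0,46500.0
536,50738.8,47575.6
538,52000.0,48500.0
540,52836.8,49276.8
542,53236.0,50000.0
544,52710.5,50787.5
546,51500.0,51500.0
548,48713.9,52043.9
550,45000.0,52500.0
552,41566.7,52973.8
554,38299.3,53351.1
556,35818.4,53392.4
558,33613.2,53249.7
560,32613.0,53000.0
562,32865.5,52245.5
564,33500.0,51000.0
566,35457.5,49501.1
568,39000.0,47500.0
570,45000.0,44500.0
572,49000.0,41500.0
574,52537.7,38716.6
576,54424.0,36000.0
578,53139.6,33217.3
580,50000.0,30500.0
582,39597.1,27814.0
584,27000.0,25500.0
586,19847.1,23906.2
588,14500.0,22500.0
590,10403.2,20980.3
592,7500.0,19500.0
594,5701.7,18091.9
596,4500.0,16800.0
598,3751.4,15692.3
600,3200.0,14677.0
602,2687.8,13676.2
604,2198.7,12691.9
606,1765.6,11740.2
608,1421.7,10837.5
610,1200.0,10000.0
612,1062.9,9188.1
614,949.8,8383.9
616,859.3,7636.7
618,789.9,6995.7
620,740.0,6510.0
622,705.2,6150.1
624,679.1,5845.9
626,657.4,5585.5
628,635.8,5357.2
630,610.0,5149.0
632,577.1,4958.1
634,539.6,4786.6
636,501.9,4630.2
638,467.9,4484.8
640,442.0,4346.0
642,423.0,4214.3
644,406.8,4091.2
646,392.6,3974.4
648,379.9,3861.4
650,368.0,3750.0
652,356.5,3639.4
654,345.8,3530.9
656,335.8,3425.5
658,327.0,3323.8
660,319.6,3226.6
662,313.3,3134.2
664,307.7,3045.8
666,302.7,2960.4
668,298.2,2877.1
670,294.0,2795.0
672,289.7,2714.2
674,285.3,2635.2
676,281.3,2557.8
678,278.4,2481.8
680,277.0,2407.0
682,276.7,2332.0
684,276.4,2256.9
686,276.2,2183.6
688,276.0,2114.3
690,276.0,2051.0
692,276.9,1994.6
694,279.2,1943.2
696,282.5,1894.3
698,286.3,1845.5
700,290.0,1794.3
702,293.5,1741.5
704,297.1,1688.8
706,301.4,1634.8
708,306.9,1578.6
710,314.0,1519.0
712,330.5,1446.6
714,359.0,1361.7
716,392.4,1277.9
718,423.8,1208.9
720,446.0,1168.0
722,459.6,1148.0
724,470.6,1131.9
726,480.2,1119.3
728,489.6,1109.5
730,500.0,1102.0
732,511.5,1095.5
734,523.3,1089.5
736,535.3,1084.6
738,547.5,1081.2
740,560.0,1080.0
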