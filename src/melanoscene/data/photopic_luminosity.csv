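# photopic luminous efficiency V(lambda) (CIE 1931 ybar column, interpolated to 1 nm)
# wavelength_nm,value
380,3.900000e-05
381,4.400000e-05
382,4.900000e-05
383,5.400000e-05
384,5.900000e-05
385,6.400000e-05
386,7.520000e-05
387,8.640000e-05
388,9.760000e-05
389,1.088000e-04
390,1.200000e-04
391,1.394000e-04
392,1.588000e-04
393,1.782000e-04
394,1.976000e-04
395,2.170000e-04
396,2.528000e-04
397,2.886000e-04
398,3.244000e-04
399,3.602000e-04
400,3.960000e-04
401,4.448000e-04
402,4.936000e-04
403,5.424000e-04
404,5.912000e-04
405,6.400000e-04
406,7.540000e-04
407,8.680000e-04
408,9.820000e-04
409,1.096000e-03
410,1.210000e-03
411,1.404000e-03
412,1.598000e-03
413,1.792000e-03
414,1.986000e-03
415,2.180000e-03
416,2.544000e-03
417,2.908000e-03
418,3.272000e-03
419,3.636000e-03
420,4.000000e-03
421,4.660000e-03
422,5.320000e-03
423,5.980000e-03
424,6.640000e-03
425,7.300000e-03
426,8.160000e-03
427,9.020000e-03
428,9.880000e-03
429,1.074000e-02
430,1.160000e-02
431,1.264800e-02
432,1.369600e-02
433,1.474400e-02
434,1.579200e-02
435,1.684000e-02
436,1.807200e-02
437,1.930400e-02
438,2.053600e-02
439,2.176800e-02
440,2.300000e-02
441,2.436000e-02
442,2.572000e-02
443,2.708000e-02
444,2.844000e-02
445,2.980000e-02
446,3.144000e-02
447,3.308000e-02
448,3.472000e-02
449,3.636000e-02
450,3.800000e-02
451,4.000000e-02
452,4.200000e-02
453,4.400000e-02
454,4.600000e-02
455,4.800000e-02
456,5.040000e-02
457,5.280000e-02
458,5.520000e-02
459,5.760000e-02
460,6.000000e-02
461,6.278000e-02
462,6.556000e-02
463,6.834000e-02
464,7.112000e-02
465,7.390000e-02
466,7.731600e-02
467,8.073200e-02
468,8.414800e-02
469,8.756400e-02
470,9.098000e-02
471,9.530400e-02
472,9.962800e-02
473,1.039520e-01
474,1.082760e-01
475,1.126000e-01
476,1.178840e-01
477,1.231680e-01
478,1.284520e-01
479,1.337360e-01
480,1.390200e-01
481,1.450760e-01
482,1.511320e-01
483,1.571880e-01
484,1.632440e-01
485,1.693000e-01
486,1.770440e-01
487,1.847880e-01
488,1.925320e-01
489,2.002760e-01
490,2.080200e-01
491,2.181360e-01
492,2.282520e-01
493,2.383680e-01
494,2.484840e-01
495,2.586000e-01
496,2.714800e-01
497,2.843600e-01
498,2.972400e-01
499,3.101200e-01
500,3.230000e-01
501,3.398600e-01
502,3.567200e-01
503,3.735800e-01
504,3.904400e-01
505,4.073000e-01
506,4.264400e-01
507,4.455800e-01
508,4.647200e-01
509,4.838600e-01
510,5.030000e-01
511,5.240400e-01
512,5.450800e-01
513,5.661200e-01
514,5.871600e-01
515,6.082000e-01
516,6.285600e-01
517,6.489200e-01
518,6.692800e-01
519,6.896400e-01
520,7.100000e-01
521,7.266400e-01
522,7.432800e-01
523,7.599200e-01
524,7.765600e-01
525,7.932000e-01
526,8.069600e-01
527,8.207200e-01
528,8.344800e-01
529,8.482400e-01
530,8.620000e-01
531,8.725700e-01
532,8.831400e-01
533,8.937100e-01
534,9.042800e-01
535,9.148500e-01
536,9.226800e-01
537,9.305100e-01
538,9.383400e-01
539,9.461700e-01
540,9.540000e-01
541,9.592600e-01
542,9.645200e-01
543,9.697800e-01
544,9.750400e-01
545,9.803000e-01
546,9.832300e-01
547,9.861600e-01
548,9.890900e-01
549,9.920200e-01
550,9.949500e-01
551,9.959600e-01
552,9.969700e-01
553,9.979800e-01
554,9.989900e-01
555,1.000000e+00
556,9.990000e-01
557,9.980000e-01
558,9.970000e-01
559,9.960000e-01
560,9.950000e-01
561,9.917200e-01
562,9.884400e-01
563,9.851600e-01
564,9.818800e-01
565,9.786000e-01
566,9.732800e-01
567,9.679600e-01
568,9.626400e-01
569,9.573200e-01
570,9.520000e-01
571,9.446800e-01
572,9.373600e-01
573,9.300400e-01
574,9.227200e-01
575,9.154000e-01
576,9.063200e-01
577,8.972400e-01
578,8.881600e-01
579,8.790800e-01
580,8.700000e-01
581,8.592600e-01
582,8.485200e-01
583,8.377800e-01
584,8.270400e-01
585,8.163000e-01
586,8.044400e-01
587,7.925800e-01
588,7.807200e-01
589,7.688600e-01
590,7.570000e-01
591,7.445800e-01
592,7.321600e-01
593,7.197400e-01
594,7.073200e-01
595,6.949000e-01
596,6.821200e-01
597,6.693400e-01
598,6.565600e-01
599,6.437800e-01
600,6.310000e-01
601,6.181600e-01
602,6.053200e-01
603,5.924800e-01
604,5.796400e-01
605,5.668000e-01
606,5.540400e-01
607,5.412800e-01
608,5.285200e-01
609,5.157600e-01
610,5.030000e-01
611,4.906400e-01
612,4.782800e-01
613,4.659200e-01
614,4.535600e-01
615,4.412000e-01
616,4.291600e-01
617,4.171200e-01
618,4.050800e-01
619,3.930400e-01
620,3.810000e-01
621,3.690000e-01
622,3.570000e-01
623,3.450000e-01
624,3.330000e-01
625,3.210000e-01
626,3.098000e-01
627,2.986000e-01
628,2.874000e-01
629,2.762000e-01
630,2.650000e-01
631,2.554000e-01
632,2.458000e-01
633,2.362000e-01
634,2.266000e-01
635,2.170000e-01
636,2.086000e-01
637,2.002000e-01
638,1.918000e-01
639,1.834000e-01
640,1.750000e-01
641,1.676400e-01
642,1.602800e-01
643,1.529200e-01
644,1.455600e-01
645,1.382000e-01
646,1.319600e-01
647,1.257200e-01
648,1.194800e-01
649,1.132400e-01
650,1.070000e-01
651,1.019200e-01
652,9.684000e-02
653,9.176000e-02
654,8.668000e-02
655,8.160000e-02
656,7.748000e-02
657,7.336000e-02
658,6.924000e-02
659,6.512000e-02
660,6.100000e-02
661,5.771600e-02
662,5.443200e-02
663,5.114800e-02
664,4.786400e-02
665,4.458000e-02
666,4.206400e-02
667,3.954800e-02
668,3.703200e-02
669,3.451600e-02
670,3.200000e-02
671,3.024000e-02
672,2.848000e-02
673,2.672000e-02
674,2.496000e-02
675,2.320000e-02
676,2.196000e-02
677,2.072000e-02
678,1.948000e-02
679,1.824000e-02
680,1.700000e-02
681,1.598400e-02
682,1.496800e-02
683,1.395200e-02
684,1.293600e-02
685,1.192000e-02
686,1.117800e-02
687,1.043600e-02
688,9.694000e-03
689,8.952000e-03
690,8.210000e-03
691,7.712600e-03
692,7.215200e-03
693,6.717800e-03
694,6.220400e-03
695,5.723000e-03
696,5.398800e-03
697,5.074600e-03
698,4.750400e-03
699,4.426200e-03
700,4.102000e-03
701,3.867400e-03
702,3.632800e-03
703,3.398200e-03
704,3.163600e-03
705,2.929000e-03
706,2.761400e-03
707,2.593800e-03
708,2.426200e-03
709,2.258600e-03
710,2.091000e-03
711,1.969600e-03
712,1.848200e-03
713,1.726800e-03
714,1.605400e-03
715,1.484000e-03
716,1.396600e-03
717,1.309200e-03
718,1.221800e-03
719,1.134400e-03
720,1.047000e-03
721,9.856000e-04
722,9.242000e-04
723,8.628000e-04
724,8.014000e-04
725,7.400000e-04
726,6.960000e-04
727,6.520000e-04
728,6.080000e-04
729,5.640000e-04
730,5.200000e-04
731,4.882000e-04
732,4.564000e-04
733,4.246000e-04
734,3.928000e-04
735,3.610000e-04
736,3.386000e-04
737,3.162000e-04
738,2.938000e-04
739,2.714000e-04
740,2.490000e-04
741,2.336000e-04
742,2.182000e-04
743,2.028000e-04
744,1.874000e-04
745,1.720000e-04
746,1.616000e-04
747,1.512000e-04
748,1.408000e-04
749,1.304000e-04
750,1.200000e-04
751,1.130000e-04
752,1.060000e-04
753,9.900000e-05
754,9.200000e-05
755,8.500000e-05
756,8.000000e-05
757,7.500000e-05
758,7.000000e-05
759,6.500000e-05
760,6.000000e-05
761,5.640000e-05
762,5.280000e-05
763,4.920000e-05
764,4.560000e-05
765,4.200000e-05
766,3.960000e-05
767,3.720000e-05
768,3.480000e-05
769,3.240000e-05
770,3.000000e-05
771,2.820000e-05
772,2.640000e-05
773,2.460000e-05
774,2.280000e-05
775,2.100000e-05
776,1.980000e-05
777,1.860000e-05
778,1.740000e-05
779,1.620000e-05
780,1.500000e-05
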