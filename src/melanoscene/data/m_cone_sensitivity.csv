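# M-cone corneal sensitivity (template: A1 nomogram x media filter; corneal peak 535 nm)
# wavelength_nm,value
380,5.803836e-03
381,6.319621e-03
382,6.863562e-03
383,7.435712e-03
384,8.036037e-03
385,8.664413e-03
386,9.320641e-03
387,1.000445e-02
388,1.071552e-02
389,1.145346e-02
390,1.221786e-02
391,1.300829e-02
392,1.382431e-02
393,1.466549e-02
394,1.553141e-02
395,1.642173e-02
396,1.733613e-02
397,1.827438e-02
398,1.923638e-02
399,2.022209e-02
400,2.123163e-02
401,2.226527e-02
402,2.332343e-02
403,2.440671e-02
404,2.551593e-02
405,2.665207e-02
406,2.781637e-02
407,2.901026e-02
408,3.023545e-02
409,3.149387e-02
410,3.278771e-02
411,3.411940e-02
412,3.549166e-02
413,3.690745e-02
414,3.837000e-02
415,3.988280e-02
416,4.144959e-02
417,4.307437e-02
418,4.476137e-02
419,4.651508e-02
420,4.834019e-02
421,5.024163e-02
422,5.222453e-02
423,5.429419e-02
424,5.645611e-02
425,5.871593e-02
426,6.107946e-02
427,6.355260e-02
428,6.614140e-02
429,6.885195e-02
430,7.169044e-02
431,7.466310e-02
432,7.777618e-02
433,8.103593e-02
434,8.444860e-02
435,8.802037e-02
436,9.175739e-02
437,9.566570e-02
438,9.975125e-02
439,1.040198e-01
440,1.084771e-01
441,1.131286e-01
442,1.179795e-01
443,1.230350e-01
444,1.282998e-01
445,1.337786e-01
446,1.394756e-01
447,1.453948e-01
448,1.515398e-01
449,1.579141e-01
450,1.645206e-01
451,1.713618e-01
452,1.784401e-01
453,1.857573e-01
454,1.933147e-01
455,2.011135e-01
456,2.091540e-01
457,2.174366e-01
458,2.259608e-01
459,2.347258e-01
460,2.437304e-01
461,2.529730e-01
462,2.624511e-01
463,2.721624e-01
464,2.821035e-01
465,2.922708e-01
466,3.026604e-01
467,3.132676e-01
468,3.240874e-01
469,3.351144e-01
470,3.463427e-01
471,3.577658e-01
472,3.693771e-01
473,3.811694e-01
474,3.931349e-01
475,4.052658e-01
476,4.175536e-01
477,4.299895e-01
478,4.425645e-01
479,4.552692e-01
480,4.680936e-01
481,4.810278e-01
482,4.940614e-01
483,5.071837e-01
484,5.203838e-01
485,5.336506e-01
486,5.469726e-01
487,5.603382e-01
488,5.737357e-01
489,5.871530e-01
490,6.005779e-01
491,6.139982e-01
492,6.274014e-01
493,6.407747e-01
494,6.541056e-01
495,6.673812e-01
496,6.805884e-01
497,6.937144e-01
498,7.067458e-01
499,7.196696e-01
500,7.324724e-01
501,7.451409e-01
502,7.576618e-01
503,7.700214e-01
504,7.822064e-01
505,7.942032e-01
506,8.059983e-01
507,8.175779e-01
508,8.289284e-01
509,8.400363e-01
510,8.508877e-01
511,8.614691e-01
512,8.717667e-01
513,8.817669e-01
514,8.914560e-01
515,9.008203e-01
516,9.098463e-01
517,9.185204e-01
518,9.268292e-01
519,9.347592e-01
520,9.422973e-01
521,9.494303e-01
522,9.561452e-01
523,9.624292e-01
524,9.682698e-01
525,9.736548e-01
526,9.785720e-01
527,9.830098e-01
528,9.869570e-01
529,9.904026e-01
530,9.933362e-01
531,9.957480e-01
532,9.976286e-01
533,9.989694e-01
534,9.997623e-01
535,1.000000e+00
536,9.996761e-01
537,9.987850e-01
538,9.973219e-01
539,9.952832e-01
540,9.926660e-01
541,9.894688e-01
542,9.856909e-01
543,9.813331e-01
544,9.763972e-01
545,9.708862e-01
546,9.648046e-01
547,9.581580e-01
548,9.509534e-01
549,9.431991e-01
550,9.349046e-01
551,9.260811e-01
552,9.167406e-01
553,9.068968e-01
554,8.965643e-01
555,8.857592e-01
556,8.744985e-01
557,8.628006e-01
558,8.506845e-01
559,8.381705e-01
560,8.252796e-01
561,8.120336e-01
562,7.984551e-01
563,7.845671e-01
564,7.703933e-01
565,7.559576e-01
566,7.412842e-01
567,7.263977e-01
568,7.113225e-01
569,6.960832e-01
570,6.807040e-01
571,6.652093e-01
572,6.496227e-01
573,6.339679e-01
574,6.182678e-01
575,6.025449e-01
576,5.868210e-01
577,5.711173e-01
578,5.554543e-01
579,5.398517e-01
580,5.243284e-01
581,5.089025e-01
582,4.935913e-01
583,4.784111e-01
584,4.633775e-01
585,4.485050e-01
586,4.338076e-01
587,4.192980e-01
588,4.049884e-01
589,3.908899e-01
590,3.770130e-01
591,3.633674e-01
592,3.499618e-01
593,3.368045e-01
594,3.239027e-01
595,3.112633e-01
596,2.988922e-01
597,2.867950e-01
598,2.749763e-01
599,2.634405e-01
600,2.521911e-01
601,2.412313e-01
602,2.305636e-01
603,2.201902e-01
604,2.101125e-01
605,2.003317e-01
606,1.908484e-01
607,1.816626e-01
608,1.727742e-01
609,1.641822e-01
610,1.558855e-01
611,1.478823e-01
612,1.401706e-01
613,1.327479e-01
614,1.256111e-01
615,1.187569e-01
616,1.121815e-01
617,1.058806e-01
618,9.984973e-02
619,9.408392e-02
620,8.857785e-02
621,8.332589e-02
622,7.832211e-02
623,7.356028e-02
624,6.903390e-02
625,6.473625e-02
626,6.066040e-02
627,5.679926e-02
628,5.314559e-02
629,4.969203e-02
630,4.643116e-02
631,4.335550e-02
632,4.045756e-02
633,3.772985e-02
634,3.516493e-02
635,3.275545e-02
636,3.049412e-02
637,2.837378e-02
638,2.638743e-02
639,2.452819e-02
640,2.278939e-02
641,2.116453e-02
642,1.964731e-02
643,1.823166e-02
644,1.691172e-02
645,1.568185e-02
646,1.453665e-02
647,1.347095e-02
648,1.247982e-02
649,1.155855e-02
650,1.070267e-02
651,9.907943e-03
652,9.170336e-03
653,8.486051e-03
654,7.851498e-03
655,7.263290e-03
656,6.718241e-03
657,6.213354e-03
658,5.745816e-03
659,5.312991e-03
660,4.912407e-03
661,4.541754e-03
662,4.198871e-03
663,3.881744e-03
664,3.588490e-03
665,3.317357e-03
666,3.066714e-03
667,2.835042e-03
668,2.620929e-03
669,2.423063e-03
670,2.240226e-03
671,2.071288e-03
672,1.915200e-03
673,1.770992e-03
674,1.637762e-03
675,1.514676e-03
676,1.400963e-03
677,1.295908e-03
678,1.198850e-03
679,1.109178e-03
680,1.026326e-03
681,9.497733e-04
682,8.790363e-04
683,8.136692e-04
684,7.532604e-04
685,6.974293e-04
686,6.458248e-04
687,5.981227e-04
688,5.540237e-04
689,5.132515e-04
690,4.755510e-04
691,4.406871e-04
692,4.084425e-04
693,3.786169e-04
694,3.510253e-04
695,3.254971e-04
696,3.018748e-04
697,2.800133e-04
698,2.597783e-04
699,2.410464e-04
700,2.237032e-04
701,2.076434e-04
702,1.927699e-04
703,1.789928e-04
704,1.662295e-04
705,1.544034e-04
706,1.434439e-04
707,1.332860e-04
708,1.238694e-04
709,1.151387e-04
710,1.070426e-04
711,9.953355e-05
712,9.256796e-05
713,8.610536e-05
714,8.010842e-05
715,7.454263e-05
716,6.937610e-05
717,6.457937e-05
718,6.012519e-05
719,5.598838e-05
720,5.214565e-05
721,4.857548e-05
722,4.525795e-05
723,4.217464e-05
724,3.930851e-05
725,3.664380e-05
726,3.416590e-05
727,3.186131e-05
728,2.971754e-05
729,2.772301e-05
730,2.586700e-05
731,2.413958e-05
732,2.253156e-05
733,2.103442e-05
734,1.964027e-05
735,1.834180e-05
736,1.713222e-05
737,1.600525e-05
738,1.495506e-05
739,1.397625e-05
740,1.306381e-05
741,1.221309e-05
742,1.141976e-05
743,1.067984e-05
744,9.989609e-06
745,9.345610e-06
746,8.744646e-06
747,8.183744e-06
748,7.660141e-06
749,7.171273e-06
750,6.714757e-06
751,6.288378e-06
752,5.890079e-06
753,5.517946e-06
754,5.170201e-06
755,4.845190e-06
756,4.541375e-06
757,4.257325e-06
758,3.991711e-06
759,3.743292e-06
760,3.510918e-06
761,3.293515e-06
762,3.090084e-06
763,2.899697e-06
764,2.721486e-06
765,2.554646e-06
766,2.398425e-06
767,2.252123e-06
768,2.115088e-06
769,1.986711e-06
770,1.866427e-06
771,1.753706e-06
772,1.648056e-06
773,1.549018e-06
774,1.456162e-06
775,1.369088e-06
776,1.287424e-06
777,1.210822e-06
778,1.138955e-06
779,1.071521e-06
780,1.008236e-06
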