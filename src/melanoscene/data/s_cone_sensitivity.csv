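# S-cone corneal sensitivity (template: A1 nomogram x media filter; corneal peak 440 nm)
# wavelength_nm,value
380,4.073614e-02
381,4.564816e-02
382,5.102220e-02
383,5.688540e-02
384,6.326474e-02
385,7.018676e-02
386,7.767744e-02
387,8.576189e-02
388,9.446419e-02
389,1.038071e-01
390,1.138118e-01
391,1.244979e-01
392,1.358826e-01
393,1.479814e-01
394,1.608068e-01
395,1.743688e-01
396,1.886746e-01
397,2.037280e-01
398,2.195297e-01
399,2.360766e-01
400,2.533622e-01
401,2.713759e-01
402,2.901030e-01
403,3.095249e-01
404,3.296187e-01
405,3.503568e-01
406,3.717076e-01
407,3.936348e-01
408,4.160977e-01
409,4.390509e-01
410,4.624448e-01
411,4.862251e-01
412,5.103333e-01
413,5.347069e-01
414,5.592788e-01
415,5.839786e-01
416,6.087318e-01
417,6.334607e-01
418,6.580846e-01
419,6.825197e-01
420,7.066801e-01
421,7.304778e-01
422,7.538232e-01
423,7.766258e-01
424,7.987945e-01
425,8.202382e-01
426,8.408663e-01
427,8.605897e-01
428,8.793207e-01
429,8.969743e-01
430,9.134686e-01
431,9.287253e-01
432,9.426703e-01
433,9.552345e-01
434,9.663546e-01
435,9.759727e-01
436,9.840380e-01
437,9.905062e-01
438,9.953407e-01
439,9.985123e-01
440,1.000000e+00
441,9.997906e-01
442,9.978794e-01
443,9.942698e-01
444,9.889737e-01
445,9.820108e-01
446,9.734092e-01
447,9.632046e-01
448,9.514403e-01
449,9.381667e-01
450,9.234412e-01
451,9.073277e-01
452,8.898959e-01
453,8.712214e-01
454,8.513847e-01
455,8.304710e-01
456,8.085697e-01
457,7.857736e-01
458,7.621788e-01
459,7.378841e-01
460,7.129899e-01
461,6.875983e-01
462,6.618123e-01
463,6.357349e-01
464,6.094689e-01
465,5.831161e-01
466,5.567764e-01
467,5.305475e-01
468,5.045240e-01
469,4.787966e-01
470,4.534520e-01
471,4.285713e-01
472,4.042304e-01
473,3.804986e-01
474,3.574389e-01
475,3.351068e-01
476,3.135508e-01
477,2.928114e-01
478,2.729216e-01
479,2.539068e-01
480,2.357847e-01
481,2.185657e-01
482,2.022531e-01
483,1.868440e-01
484,1.723290e-01
485,1.586936e-01
486,1.459181e-01
487,1.339786e-01
488,1.228478e-01
489,1.124952e-01
490,1.028880e-01
491,9.399147e-02
492,8.576995e-02
493,7.818686e-02
494,7.120544e-02
495,6.478903e-02
496,5.890152e-02
497,5.350755e-02
498,4.857283e-02
499,4.406430e-02
500,3.995027e-02
501,3.620058e-02
502,3.278663e-02
503,2.968144e-02
504,2.685967e-02
505,2.429760e-02
506,2.197311e-02
507,1.986565e-02
508,1.795618e-02
509,1.622708e-02
510,1.466214e-02
511,1.324641e-02
512,1.196621e-02
513,1.080898e-02
514,9.763241e-03
515,8.818513e-03
516,7.965240e-03
517,7.194724e-03
518,6.499050e-03
519,5.871032e-03
520,5.304147e-03
521,4.792481e-03
522,4.330675e-03
523,3.913879e-03
524,3.537705e-03
525,3.198186e-03
526,2.891735e-03
527,2.615115e-03
528,2.365400e-03
529,2.139953e-03
530,1.936392e-03
531,1.752568e-03
532,1.586546e-03
533,1.436577e-03
534,1.301089e-03
535,1.178660e-03
536,1.068013e-03
537,9.679946e-04
538,8.775652e-04
539,7.957887e-04
540,7.218212e-04
541,6.549023e-04
542,5.943464e-04
543,5.395358e-04
544,4.899137e-04
545,4.449779e-04
546,4.042758e-04
547,3.673993e-04
548,3.339803e-04
549,3.036868e-04
550,2.762194e-04
551,2.513079e-04
552,2.287084e-04
553,2.082009e-04
554,1.895866e-04
555,1.726862e-04
556,1.573377e-04
557,1.433948e-04
558,1.307252e-04
559,1.192095e-04
560,1.087396e-04
561,9.921795e-05
562,9.055621e-05
563,8.267451e-05
564,7.550059e-05
565,6.896906e-05
566,6.302071e-05
567,5.760195e-05
568,5.266424e-05
569,4.816360e-05
570,4.406018e-05
571,4.031788e-05
572,3.690395e-05
573,3.378870e-05
574,3.094521e-05
575,2.834903e-05
576,2.597799e-05
577,2.381196e-05
578,2.183266e-05
579,2.002349e-05
580,1.836936e-05
581,1.685657e-05
582,1.547265e-05
583,1.420628e-05
584,1.304716e-05
585,1.198590e-05
586,1.101398e-05
587,1.012364e-05
588,9.307795e-06
589,8.560020e-06
590,7.874447e-06
591,7.245731e-06
592,6.669001e-06
593,6.139816e-06
594,5.654127e-06
595,5.208238e-06
596,4.798780e-06
597,4.422676e-06
598,4.077118e-06
599,3.759541e-06
600,3.467603e-06
601,3.199163e-06
602,2.952266e-06
603,2.725123e-06
604,2.516101e-06
605,2.323703e-06
606,2.146563e-06
607,1.983428e-06
608,1.833152e-06
609,1.694688e-06
610,1.567074e-06
611,1.449429e-06
612,1.340949e-06
613,1.240895e-06
614,1.148588e-06
615,1.063407e-06
616,9.847841e-07
617,9.121952e-07
618,8.451611e-07
619,7.832416e-07
620,7.260325e-07
621,6.731627e-07
622,6.242911e-07
623,5.791047e-07
624,5.373154e-07
625,4.986587e-07
626,4.628913e-07
627,4.297893e-07
628,3.991470e-07
629,3.707748e-07
630,3.444985e-07
631,3.201576e-07
632,2.976042e-07
633,2.767024e-07
634,2.573266e-07
635,2.393614e-07
636,2.227003e-07
637,2.072451e-07
638,1.929052e-07
639,1.795973e-07
640,1.672442e-07
641,1.557749e-07
642,1.451238e-07
643,1.352303e-07
644,1.260385e-07
645,1.174968e-07
646,1.095575e-07
647,1.021764e-07
648,9.531288e-08
649,8.892920e-08
650,8.299056e-08
651,7.746475e-08
652,7.232197e-08
653,6.753466e-08
654,6.307730e-08
655,5.892629e-08
656,5.505974e-08
657,5.145742e-08
658,4.810058e-08
659,4.497183e-08
660,4.205509e-08
661,3.933541e-08
662,3.679898e-08
663,3.443296e-08
664,3.222545e-08
665,3.016543e-08
666,2.824265e-08
667,2.644760e-08
668,2.477148e-08
669,2.320608e-08
670,2.174381e-08
671,2.037760e-08
672,1.910090e-08
673,1.790759e-08
674,1.679203e-08
675,1.574895e-08
676,1.477344e-08
677,1.386095e-08
678,1.300726e-08
679,1.220841e-08
680,1.146075e-08
681,1.076086e-08
682,1.010556e-08
683,9.491910e-09
684,8.917143e-09
685,8.378700e-09
686,7.874191e-09
687,7.401391e-09
688,6.958225e-09
689,6.542760e-09
690,6.153194e-09
691,5.787847e-09
692,5.445150e-09
693,5.123642e-09
694,4.821959e-09
695,4.538829e-09
696,4.273062e-09
697,4.023550e-09
698,3.789258e-09
699,3.569219e-09
700,3.362530e-09
701,3.168346e-09
702,2.985881e-09
703,2.814396e-09
704,2.653205e-09
705,2.501662e-09
706,2.359166e-09
707,2.225155e-09
708,2.099102e-09
709,1.980514e-09
710,1.868931e-09
711,1.763921e-09
712,1.665081e-09
713,1.572033e-09
714,1.484423e-09
715,1.401919e-09
716,1.324212e-09
717,1.251011e-09
718,1.182042e-09
719,1.117052e-09
720,1.055800e-09
721,9.980627e-10
722,9.436293e-10
723,8.923027e-10
724,8.438979e-10
725,7.982414e-10
726,7.551704e-10
727,7.145322e-10
728,6.761834e-10
729,6.399894e-10
730,6.058238e-10
731,5.735680e-10
732,5.431106e-10
733,5.143470e-10
734,4.871787e-10
735,4.615136e-10
736,4.372646e-10
737,4.143504e-10
738,3.926940e-10
739,3.722236e-10
740,3.528712e-10
741,3.345730e-10
742,3.172692e-10
743,3.009033e-10
744,2.854221e-10
745,2.707757e-10
746,2.569172e-10
747,2.438021e-10
748,2.313890e-10
749,2.196384e-10
750,2.085135e-10
751,1.979794e-10
752,1.880035e-10
753,1.785546e-10
754,1.696039e-10
755,1.611237e-10
756,1.530883e-10
757,1.454732e-10
758,1.382556e-10
759,1.314136e-10
760,1.249269e-10
761,1.187762e-10
762,1.129432e-10
763,1.074109e-10
764,1.021630e-10
765,9.718414e-11
766,9.246000e-11
767,8.797693e-11
768,8.372205e-11
769,7.968322e-11
770,7.584895e-11
771,7.220841e-11
772,6.875136e-11
773,6.546812e-11
774,6.234955e-11
775,5.938701e-11
776,5.657232e-11
777,5.389776e-11
778,5.135604e-11
779,4.894025e-11
780,4.664385e-11
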