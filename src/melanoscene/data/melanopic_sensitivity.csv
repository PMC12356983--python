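# melanopic corneal sensitivity (template: A1 nomogram x media filter; corneal peak 490 nm)
# wavelength_nm,value
380,6.966445e-03
381,7.650793e-03
382,8.389323e-03
383,9.185731e-03
384,1.004398e-02
385,1.096834e-02
386,1.196335e-02
387,1.303390e-02
388,1.418520e-02
389,1.542282e-02
390,1.675267e-02
391,1.818103e-02
392,1.971454e-02
393,2.136023e-02
394,2.312548e-02
395,2.501804e-02
396,2.704600e-02
397,2.921781e-02
398,3.154223e-02
399,3.402834e-02
400,3.668549e-02
401,3.952329e-02
402,4.255156e-02
403,4.578033e-02
404,4.921974e-02
405,5.288008e-02
406,5.677166e-02
407,6.090484e-02
408,6.528991e-02
409,6.993710e-02
410,7.485647e-02
411,8.005791e-02
412,8.555104e-02
413,9.134516e-02
414,9.744921e-02
415,1.038717e-01
416,1.106207e-01
417,1.177037e-01
418,1.251275e-01
419,1.328985e-01
420,1.410223e-01
421,1.495035e-01
422,1.583464e-01
423,1.675542e-01
424,1.771291e-01
425,1.870727e-01
426,1.973854e-01
427,2.080670e-01
428,2.191160e-01
429,2.305300e-01
430,2.423056e-01
431,2.544385e-01
432,2.669232e-01
433,2.797533e-01
434,2.929213e-01
435,3.064186e-01
436,3.202359e-01
437,3.343627e-01
438,3.487873e-01
439,3.634976e-01
440,3.784800e-01
441,3.937203e-01
442,4.092033e-01
443,4.249131e-01
444,4.408326e-01
445,4.569444e-01
446,4.732299e-01
447,4.896699e-01
448,5.062446e-01
449,5.229333e-01
450,5.397150e-01
451,5.565677e-01
452,5.734690e-01
453,5.903959e-01
454,6.073250e-01
455,6.242323e-01
456,6.410934e-01
457,6.578833e-01
458,6.745768e-01
459,6.911482e-01
460,7.075716e-01
461,7.238207e-01
462,7.398688e-01
463,7.556892e-01
464,7.712548e-01
465,7.865384e-01
466,8.015126e-01
467,8.161500e-01
468,8.304230e-01
469,8.443041e-01
470,8.577659e-01
471,8.707809e-01
472,8.833219e-01
473,8.953619e-01
474,9.068742e-01
475,9.178323e-01
476,9.282105e-01
477,9.379832e-01
478,9.471259e-01
479,9.556144e-01
480,9.634255e-01
481,9.705370e-01
482,9.769277e-01
483,9.825776e-01
484,9.874679e-01
485,9.915812e-01
486,9.949017e-01
487,9.974153e-01
488,9.991096e-01
489,9.999740e-01
490,1.000000e+00
491,9.991813e-01
492,9.975135e-01
493,9.949949e-01
494,9.916257e-01
495,9.874089e-01
496,9.823498e-01
497,9.764562e-01
498,9.697384e-01
499,9.622094e-01
500,9.538843e-01
501,9.447810e-01
502,9.349197e-01
503,9.243227e-01
504,9.130148e-01
505,9.010228e-01
506,8.883752e-01
507,8.751025e-01
508,8.612370e-01
509,8.468122e-01
510,8.318629e-01
511,8.164251e-01
512,8.005356e-01
513,7.842320e-01
514,7.675522e-01
515,7.505346e-01
516,7.332176e-01
517,7.156395e-01
518,6.978383e-01
519,6.798517e-01
520,6.617167e-01
521,6.434697e-01
522,6.251461e-01
523,6.067805e-01
524,5.884062e-01
525,5.700557e-01
526,5.517599e-01
527,5.335488e-01
528,5.154507e-01
529,4.974929e-01
530,4.797012e-01
531,4.621001e-01
532,4.447126e-01
533,4.275604e-01
534,4.106640e-01
535,3.940424e-01
536,3.777134e-01
537,3.616936e-01
538,3.459981e-01
539,3.306410e-01
540,3.156352e-01
541,3.009923e-01
542,2.867229e-01
543,2.728363e-01
544,2.593407e-01
545,2.462432e-01
546,2.335500e-01
547,2.212658e-01
548,2.093945e-01
549,1.979387e-01
550,1.869002e-01
551,1.762795e-01
552,1.660759e-01
553,1.562879e-01
554,1.469129e-01
555,1.379472e-01
556,1.293860e-01
557,1.212239e-01
558,1.134541e-01
559,1.060693e-01
560,9.906127e-02
561,9.242095e-02
562,8.613865e-02
563,8.020405e-02
564,7.460629e-02
565,6.933402e-02
566,6.437553e-02
567,5.971876e-02
568,5.535146e-02
569,5.126122e-02
570,4.743553e-02
571,4.386190e-02
572,4.052790e-02
573,3.742124e-02
574,3.452979e-02
575,3.184167e-02
576,2.934530e-02
577,2.702939e-02
578,2.488304e-02
579,2.289572e-02
580,2.105729e-02
581,1.935807e-02
582,1.778879e-02
583,1.634061e-02
584,1.500517e-02
585,1.377453e-02
586,1.264118e-02
587,1.159806e-02
588,1.063852e-02
589,9.756322e-03
590,8.945623e-03
591,8.200959e-03
592,7.517232e-03
593,6.889692e-03
594,6.313919e-03
595,5.785808e-03
596,5.301551e-03
597,4.857618e-03
598,4.450745e-03
599,4.077912e-03
600,3.736331e-03
601,3.423430e-03
602,3.136839e-03
603,2.874372e-03
604,2.634021e-03
605,2.413937e-03
606,2.212421e-03
607,2.027913e-03
608,1.858979e-03
609,1.704305e-03
610,1.562686e-03
611,1.433015e-03
612,1.314281e-03
613,1.205554e-03
614,1.105986e-03
615,1.014796e-03
616,9.312744e-04
617,8.547677e-04
618,7.846796e-04
619,7.204643e-04
620,6.616227e-04
621,6.076981e-04
622,5.582730e-04
623,5.129654e-04
624,4.714262e-04
625,4.333361e-04
626,3.984030e-04
627,3.663602e-04
628,3.369634e-04
629,3.099895e-04
630,2.852344e-04
631,2.625115e-04
632,2.416500e-04
633,2.224940e-04
634,2.049006e-04
635,1.887391e-04
636,1.738903e-04
637,1.602446e-04
638,1.477022e-04
639,1.361714e-04
640,1.255686e-04
641,1.158170e-04
642,1.068464e-04
643,9.859248e-05
644,9.099647e-05
645,8.400443e-05
646,7.756694e-05
647,7.163877e-05
648,6.617845e-05
649,6.114796e-05
650,5.651248e-05
651,5.224007e-05
652,4.830142e-05
653,4.466969e-05
654,4.132022e-05
655,3.823040e-05
656,3.537949e-05
657,3.274844e-05
658,3.031976e-05
659,2.807740e-05
660,2.600662e-05
661,2.409386e-05
662,2.232669e-05
663,2.069366e-05
664,1.918427e-05
665,1.778886e-05
666,1.649853e-05
667,1.530512e-05
668,1.420110e-05
669,1.317957e-05
670,1.223415e-05
671,1.135898e-05
672,1.054868e-05
673,9.798264e-06
674,9.103169e-06
675,8.459177e-06
676,7.862403e-06
677,7.309269e-06
678,6.796475e-06
679,6.320978e-06
680,5.879973e-06
681,5.470872e-06
682,5.091288e-06
683,4.739018e-06
684,4.412028e-06
685,4.108442e-06
686,3.826525e-06
687,3.564678e-06
688,3.321422e-06
689,3.095390e-06
690,2.885321e-06
691,2.690046e-06
692,2.508488e-06
693,2.339649e-06
694,2.182606e-06
695,2.036506e-06
696,1.900560e-06
697,1.774036e-06
698,1.656257e-06
699,1.546599e-06
700,1.444480e-06
701,1.349365e-06
702,1.260754e-06
703,1.178188e-06
704,1.101239e-06
705,1.029511e-06
706,9.626368e-07
707,9.002762e-07
708,8.421133e-07
709,7.878554e-07
710,7.372305e-07
711,6.899865e-07
712,6.458893e-07
713,6.047216e-07
714,5.662816e-07
715,5.303818e-07
716,4.968483e-07
717,4.655192e-07
718,4.362442e-07
719,4.088837e-07
720,3.833077e-07
721,3.593956e-07
722,3.370350e-07
723,3.161215e-07
724,2.965580e-07
725,2.782539e-07
726,2.611252e-07
727,2.450936e-07
728,2.300860e-07
729,2.160347e-07
730,2.028764e-07
731,1.905522e-07
732,1.790072e-07
733,1.681902e-07
734,1.580536e-07
735,1.485529e-07
736,1.396468e-07
737,1.312966e-07
738,1.234662e-07
739,1.161221e-07
740,1.092329e-07
741,1.027694e-07
742,9.670410e-08
743,9.101166e-08
744,8.566824e-08
745,8.065160e-08
746,7.594098e-08
747,7.151698e-08
748,6.736150e-08
749,6.345758e-08
750,5.978941e-08
751,5.634220e-08
752,5.310210e-08
753,5.005619e-08
754,4.719237e-08
755,4.449933e-08
756,4.196647e-08
757,3.958390e-08
758,3.734234e-08
759,3.523312e-08
760,3.324812e-08
761,3.137972e-08
762,2.962080e-08
763,2.796470e-08
764,2.640516e-08
765,2.493633e-08
766,2.355272e-08
767,2.224919e-08
768,2.102091e-08
769,1.986337e-08
770,1.877233e-08
771,1.774381e-08
772,1.677409e-08
773,1.585967e-08
774,1.499727e-08
775,1.418381e-08
776,1.341639e-08
777,1.269231e-08
778,1.200903e-08
779,1.136413e-08
780,1.075539e-08
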