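# L-cone corneal sensitivity (template: A1 nomogram x media filter; corneal peak 565 nm)
# wavelength_nm,value
380,5.911932e-03
381,6.460704e-03
382,7.041596e-03
383,7.654731e-03
384,8.300084e-03
385,8.977481e-03
386,9.686594e-03
387,1.042695e-02
388,1.119791e-02
389,1.199872e-02
390,1.282847e-02
391,1.368609e-02
392,1.457043e-02
393,1.548019e-02
394,1.641397e-02
395,1.737029e-02
396,1.834757e-02
397,1.934418e-02
398,2.035841e-02
399,2.138854e-02
400,2.243281e-02
401,2.348946e-02
402,2.455676e-02
403,2.563297e-02
404,2.671643e-02
405,2.780552e-02
406,2.889870e-02
407,2.999454e-02
408,3.109170e-02
409,3.218898e-02
410,3.328530e-02
411,3.437975e-02
412,3.547157e-02
413,3.656018e-02
414,3.764519e-02
415,3.872639e-02
416,3.980380e-02
417,4.087762e-02
418,4.194829e-02
419,4.301644e-02
420,4.408297e-02
421,4.514896e-02
422,4.621575e-02
423,4.728488e-02
424,4.835816e-02
425,4.943758e-02
426,5.052538e-02
427,5.162402e-02
428,5.273614e-02
429,5.386464e-02
430,5.501258e-02
431,5.618323e-02
432,5.738007e-02
433,5.860671e-02
434,5.986698e-02
435,6.116484e-02
436,6.250441e-02
437,6.388995e-02
438,6.532585e-02
439,6.681661e-02
440,6.836687e-02
441,6.998132e-02
442,7.166477e-02
443,7.342208e-02
444,7.525818e-02
445,7.717806e-02
446,7.918672e-02
447,8.128920e-02
448,8.349056e-02
449,8.579585e-02
450,8.821010e-02
451,9.073833e-02
452,9.338552e-02
453,9.615659e-02
454,9.905643e-02
455,1.020898e-01
456,1.052615e-01
457,1.085760e-01
458,1.120380e-01
459,1.156518e-01
460,1.194216e-01
461,1.233517e-01
462,1.274459e-01
463,1.317081e-01
464,1.361420e-01
465,1.407511e-01
466,1.455385e-01
467,1.505074e-01
468,1.556607e-01
469,1.610010e-01
470,1.665307e-01
471,1.722520e-01
472,1.781668e-01
473,1.842769e-01
474,1.905837e-01
475,1.970883e-01
476,2.037916e-01
477,2.106943e-01
478,2.177966e-01
479,2.250987e-01
480,2.326002e-01
481,2.403006e-01
482,2.481990e-01
483,2.562942e-01
484,2.645849e-01
485,2.730692e-01
486,2.817449e-01
487,2.906098e-01
488,2.996611e-01
489,3.088958e-01
490,3.183104e-01
491,3.279015e-01
492,3.376650e-01
493,3.475968e-01
494,3.576921e-01
495,3.679463e-01
496,3.783543e-01
497,3.889105e-01
498,3.996093e-01
499,4.104449e-01
500,4.214110e-01
501,4.325011e-01
502,4.437086e-01
503,4.550265e-01
504,4.664478e-01
505,4.779649e-01
506,4.895705e-01
507,5.012566e-01
508,5.130154e-01
509,5.248387e-01
510,5.367183e-01
511,5.486456e-01
512,5.606121e-01
513,5.726091e-01
514,5.846277e-01
515,5.966589e-01
516,6.086937e-01
517,6.207228e-01
518,6.327369e-01
519,6.447268e-01
520,6.566829e-01
521,6.685958e-01
522,6.804559e-01
523,6.922534e-01
524,7.039788e-01
525,7.156223e-01
526,7.271742e-01
527,7.386245e-01
528,7.499634e-01
529,7.611811e-01
530,7.722676e-01
531,7.832129e-01
532,7.940071e-01
533,8.046402e-01
534,8.151021e-01
535,8.253828e-01
536,8.354723e-01
537,8.453603e-01
538,8.550370e-01
539,8.644920e-01
540,8.737154e-01
541,8.826969e-01
542,8.914264e-01
543,8.998939e-01
544,9.080891e-01
545,9.160020e-01
546,9.236224e-01
547,9.309403e-01
548,9.379457e-01
549,9.446286e-01
550,9.509790e-01
551,9.569871e-01
552,9.626431e-01
553,9.679375e-01
554,9.728607e-01
555,9.774033e-01
556,9.815562e-01
557,9.853103e-01
558,9.886570e-01
559,9.915876e-01
560,9.940940e-01
561,9.961684e-01
562,9.978031e-01
563,9.989910e-01
564,9.997253e-01
565,1.000000e+00
566,9.998092e-01
567,9.991477e-01
568,9.980109e-01
569,9.963948e-01
570,9.942963e-01
571,9.917126e-01
572,9.886419e-01
573,9.850832e-01
574,9.810363e-01
575,9.765017e-01
576,9.714811e-01
577,9.659768e-01
578,9.599922e-01
579,9.535317e-01
580,9.466004e-01
581,9.392048e-01
582,9.313521e-01
583,9.230504e-01
584,9.143092e-01
585,9.051385e-01
586,8.955495e-01
587,8.855543e-01
588,8.751658e-01
589,8.643979e-01
590,8.532652e-01
591,8.417832e-01
592,8.299680e-01
593,8.178364e-01
594,8.054057e-01
595,7.926941e-01
596,7.797198e-01
597,7.665017e-01
598,7.530589e-01
599,7.394108e-01
600,7.255770e-01
601,7.115773e-01
602,6.974312e-01
603,6.831586e-01
604,6.687789e-01
605,6.543116e-01
606,6.397759e-01
607,6.251905e-01
608,6.105740e-01
609,5.959444e-01
610,5.813195e-01
611,5.667162e-01
612,5.521512e-01
613,5.376406e-01
614,5.231996e-01
615,5.088431e-01
616,4.945851e-01
617,4.804392e-01
618,4.664182e-01
619,4.525342e-01
620,4.387985e-01
621,4.252221e-01
622,4.118150e-01
623,3.985867e-01
624,3.855461e-01
625,3.727012e-01
626,3.600597e-01
627,3.476286e-01
628,3.354143e-01
629,3.234227e-01
630,3.116590e-01
631,3.001282e-01
632,2.888346e-01
633,2.777819e-01
634,2.669737e-01
635,2.564128e-01
636,2.461018e-01
637,2.360430e-01
638,2.262379e-01
639,2.166881e-01
640,2.073945e-01
641,1.983577e-01
642,1.895782e-01
643,1.810558e-01
644,1.727903e-01
645,1.647809e-01
646,1.570266e-01
647,1.495261e-01
648,1.422778e-01
649,1.352796e-01
650,1.285294e-01
651,1.220246e-01
652,1.157623e-01
653,1.097393e-01
654,1.039523e-01
655,9.839742e-02
656,9.307078e-02
657,8.796811e-02
658,8.308492e-02
659,7.841651e-02
660,7.395795e-02
661,6.970410e-02
662,6.564966e-02
663,6.178915e-02
664,5.811698e-02
665,5.462740e-02
666,5.131459e-02
667,4.817263e-02
668,4.519557e-02
669,4.237740e-02
670,3.971211e-02
671,3.719370e-02
672,3.481619e-02
673,3.257364e-02
674,3.046020e-02
675,2.847008e-02
676,2.659759e-02
677,2.483716e-02
678,2.318332e-02
679,2.163078e-02
680,2.017435e-02
681,1.880902e-02
682,1.752994e-02
683,1.633240e-02
684,1.521190e-02
685,1.416409e-02
686,1.318479e-02
687,1.227001e-02
688,1.141593e-02
689,1.061891e-02
690,9.875468e-03
691,9.182307e-03
692,8.536289e-03
693,7.934439e-03
694,7.373941e-03
695,6.852130e-03
696,6.366492e-03
697,5.914653e-03
698,5.494377e-03
699,5.103561e-03
700,4.740226e-03
701,4.402514e-03
702,4.088682e-03
703,3.797094e-03
704,3.526221e-03
705,3.274628e-03
706,3.040975e-03
707,2.824010e-03
708,2.622562e-03
709,2.435539e-03
710,2.261923e-03
711,2.100763e-03
712,1.951175e-03
713,1.812333e-03
714,1.683470e-03
715,1.563871e-03
716,1.452873e-03
717,1.349856e-03
718,1.254247e-03
719,1.165512e-03
720,1.083154e-03
721,1.006713e-03
722,9.357613e-04
723,8.699016e-04
724,8.087655e-04
725,7.520107e-04
726,6.993200e-04
727,6.503988e-04
728,6.049741e-04
729,5.627926e-04
730,5.236193e-04
731,4.872365e-04
732,4.534421e-04
733,4.220489e-04
734,3.928832e-04
735,3.657842e-04
736,3.406026e-04
737,3.172000e-04
738,2.954483e-04
739,2.752285e-04
740,2.564304e-04
741,2.389520e-04
742,2.226984e-04
743,2.075819e-04
744,1.935211e-04
745,1.804405e-04
746,1.682700e-04
747,1.569448e-04
748,1.464048e-04
749,1.365940e-04
750,1.274607e-04
751,1.189570e-04
752,1.110382e-04
753,1.036630e-04
754,9.679318e-05
755,9.039305e-05
756,8.442963e-05
757,7.887229e-05
758,7.369258e-05
759,6.886411e-05
760,6.436238e-05
761,6.016463e-05
762,5.624972e-05
763,5.259803e-05
764,4.919134e-05
765,4.601272e-05
766,4.304643e-05
767,4.027786e-05
768,3.769341e-05
769,3.528048e-05
770,3.302732e-05
771,3.092302e-05
772,2.895744e-05
773,2.712115e-05
774,2.540537e-05
775,2.380193e-05
776,2.230326e-05
777,2.090227e-05
778,1.959241e-05
779,1.836754e-05
780,1.722197e-05
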