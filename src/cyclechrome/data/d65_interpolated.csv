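# CIE standard illuminant D65 relative spectral power, PCHIP
# interpolation of the 10 nm tabulation (100 at 560 nm).
# Generated by scripts/make_standard_curves.py.
wavelength_nm,power
400,82.7549
401,83.952753
402,85.112938
403,86.222519
404,87.268559
405,88.238121
406,89.11827
407,89.896069
408,90.558581
409,91.09287
410,91.486
411,91.798255
412,92.095708
413,92.374103
414,92.629184
415,92.856697
416,93.052387
417,93.211997
418,93.331273
419,93.405959
420,93.4318
421,93.242814
422,92.729852
423,91.973908
424,91.055976
425,90.05705
426,89.058124
427,88.140192
428,87.384248
429,86.871286
430,86.6823
431,87.060363
432,88.107336
433,89.692394
434,91.684715
435,93.953473
436,96.367846
437,98.797009
438,101.11014
439,103.17641
440,104.865
441,106.37091
442,107.94347
443,109.5334
444,111.0914
445,112.56816
446,113.91439
447,115.08078
448,116.01805
449,116.67689
450,117.008
451,117.15267
452,117.28466
453,117.40336
454,117.50818
455,117.59852
456,117.67377
457,117.73335
458,117.77664
459,117.80306
460,117.812
461,117.72937
462,117.5051
463,117.17458
464,116.77325
465,116.3365
466,115.89975
467,115.49842
468,115.1679
469,114.94363
470,114.861
471,114.89074
472,114.97145
473,115.09039
474,115.23482
475,115.392
476,115.54918
477,115.69361
478,115.81255
479,115.89326
480,115.923
481,115.72386
482,115.18335
483,114.38681
484,113.41958
485,112.367
486,111.31442
487,110.34719
488,109.55065
489,109.01014
490,108.811
491,108.8262
492,108.86747
493,108.92829
494,109.00214
495,109.0825
496,109.16286
497,109.23671
498,109.29753
499,109.3388
500,109.354
501,109.32898
502,109.25814
503,109.14782
504,109.00435
505,108.83406
506,108.64328
507,108.43836
508,108.22561
509,108.01138
510,107.802
511,107.55174
512,107.22655
513,106.85028
514,106.4468
515,106.03994
516,105.65357
517,105.31154
518,105.0377
519,104.8559
520,104.79
521,104.87117
522,105.0915
523,105.41618
524,105.81045
525,106.2395
526,106.66855
527,107.06282
528,107.3875
529,107.60783
530,107.689
531,107.60287
532,107.36818
533,107.02043
534,106.59517
535,106.12791
536,105.65417
537,105.20949
538,104.82938
539,104.54938
540,104.405
541,104.34846
542,104.30592
543,104.27386
544,104.24874
545,104.22703
546,104.2052
547,104.17971
548,104.14704
549,104.10365
550,104.046
551,103.91391
552,103.66389
553,103.31745
554,102.89611
555,102.42138
556,101.91478
557,101.39783
558,100.89204
559,100.41892
560,100
561,99.594346
562,99.156825
563,98.702644
564,98.247009
565,97.805127
566,97.392202
567,97.02344
568,96.714049
569,96.479234
570,96.3342
571,96.251026
572,96.188161
573,96.140368
574,96.102412
575,96.069056
576,96.035063
577,95.995198
578,95.944223
579,95.876903
580,95.788
581,95.506967
582,94.919509
583,94.104766
584,93.141883
585,92.110001
586,91.088263
587,90.155812
588,89.391789
589,88.875338
590,88.6856
591,88.722577
592,88.822942
593,88.97085
594,89.150451
595,89.3459
596,89.541349
597,89.72095
598,89.868858
599,89.969223
600,90.0062
601,90.000836
602,89.985319
603,89.960511
604,89.927274
605,89.886469
606,89.838959
607,89.785605
608,89.727269
609,89.664814
610,89.5991
611,89.51548
612,89.400626
613,89.257382
614,89.088594
615,88.897105
616,88.685759
617,88.457402
618,88.214877
619,87.961028
620,87.6987
621,87.360066
622,86.900057
623,86.355658
624,85.763853
625,85.161626
626,84.585961
627,84.073841
628,83.662252
629,83.388177
630,83.2886
631,83.300097
632,83.331302
633,83.37729
634,83.433131
635,83.4939
636,83.554669
637,83.61051
638,83.656498
639,83.687703
640,83.6992
641,83.596373
642,83.31727
643,82.905962
644,82.406515
645,81.863
646,81.319485
647,80.820038
648,80.40873
649,80.129627
650,80.0268
651,80.02781
652,80.030807
653,80.035745
654,80.042576
655,80.051254
656,80.061732
657,80.073963
658,80.087899
659,80.103494
660,80.1207
661,80.195676
662,80.368074
663,80.613089
664,80.905914
665,81.221746
666,81.535778
667,81.823204
668,82.059221
669,82.219021
670,82.2778
671,82.215001
672,82.036765
673,81.758335
674,81.394952
675,80.961858
676,80.474296
677,79.947507
678,79.396733
679,78.837217
680,78.2842
681,77.603243
682,76.696459
683,75.633924
684,74.48571
685,73.321892
686,72.212541
687,71.227734
688,70.437542
689,69.912039
690,69.7213
691,69.723188
692,69.736402
693,69.772271
694,69.842119
695,69.957275
696,70.129065
697,70.368815
698,70.687854
699,71.097506
700,71.6091
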