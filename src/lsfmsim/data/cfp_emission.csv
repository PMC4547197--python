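wavelength_nm,value
300,0
302,0
304,0
306,0
308,0
310,0
312,0
314,0
316,0
318,0
320,0
322,0
324,0
326,0
328,0
330,0
332,0
334,0
336,0
338,0
340,0
342,0
344,0
346,0
348,0
350,0
352,0
354,0
356,0
358,0
360,0
362,0
364,0
366,0
368,0
370,0
372,0
374,0
376,0
378,1.43993e-06
380,2.14162e-06
382,3.16524e-06
384,4.6489e-06
386,6.78585e-06
388,9.8448e-06
390,1.41976e-05
392,2.03565e-05
394,2.90253e-05
396,4.11687e-05
398,5.81096e-05
400,8.16655e-05
402,0.000114342
404,0.000159614
406,0.000222329
408,0.000309303
410,0.00043018
412,0.00059868
414,0.00083438
416,0.00116522
418,0.00163095
420,0.00228777
422,0.00321436
424,0.00451952
426,0.00635135
428,0.0089079
430,0.0124486
432,0.0173057
434,0.0238938
436,0.032716
438,0.0443638
440,0.0595076
442,0.0788761
444,0.103221
446,0.133266
448,0.169645
450,0.212824
452,0.263016
454,0.320108
456,0.383584
458,0.452483
460,0.525383
462,0.600426
464,0.675391
466,0.747807
468,0.815104
470,0.874789
472,0.924628
474,0.96282
476,0.988133
478,1
480,0.998553
482,0.984595
484,0.959514
486,0.925149
488,0.88363
490,0.837193
492,0.788018
494,0.738078
496,0.68903
498,0.642149
500,0.598301
502,0.557962
504,0.521263
506,0.488057
508,0.457997
510,0.430619
512,0.405405
514,0.381848
516,0.359495
518,0.337972
520,0.316999
522,0.296393
524,0.276059
526,0.255976
528,0.236185
530,0.216769
532,0.197834
534,0.179503
536,0.161895
538,0.145124
540,0.129284
542,0.114454
544,0.100687
546,0.0880155
548,0.0764509
550,0.0659838
552,0.0565873
554,0.0482198
556,0.0408277
558,0.0343484
560,0.0287131
562,0.0238492
564,0.0196829
566,0.0161408
568,0.0131517
570,0.0106478
572,0.00856555
574,0.00684658
576,0.00543766
578,0.00429112
580,0.00336473
582,0.00262151
584,0.00202942
586,0.00156103
588,0.00119309
590,0.000906059
592,0.00068369
594,0.000512604
596,0.000381879
598,0.000282677
600,0.00020791
602,0.000151943
604,0.000110333
606,7.96071e-05
608,5.70714e-05
610,4.06543e-05
612,2.87749e-05
614,2.02368e-05
616,1.41414e-05
618,9.81885e-06
620,6.77408e-06
622,4.64366e-06
624,3.16295e-06
626,2.14064e-06
628,1.43951e-06
630,0
632,0
634,0
636,0
638,0
640,0
642,0
644,0
646,0
648,0
650,0
652,0
654,0
656,0
658,0
660,0
662,0
664,0
666,0
668,0
670,0
672,0
674,0
676,0
678,0
680,0
682,0
684,0
686,0
688,0
690,0
692,0
694,0
696,0
698,0
700,0
702,0
704,0
706,0
708,0
710,0
712,0
714,0
716,0
718,0
720,0
722,0
724,0
726,0
728,0
730,0
732,0
734,0
736,0
738,0
740,0
742,0
744,0
746,0
748,0
750,0
752,0
754,0
756,0
758,0
760,0
762,0
764,0
766,0
768,0
770,0
772,0
774,0
776,0
778,0
780,0
782,0
784,0
786,0
788,0
790,0
792,0
794,0
796,0
798,0
800,0
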