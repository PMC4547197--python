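wavelength_nm,value
300,1.11798e-06
302,1.83404e-06
304,2.9788e-06
306,4.78995e-06
308,7.62566e-06
310,1.20194e-05
312,1.87561e-05
314,2.89775e-05
316,4.43237e-05
318,6.71225e-05
320,0.000100637
322,0.000149384
324,0.000219537
326,0.000319424
328,0.000460135
330,0.000656235
332,0.000926598
334,0.00129533
336,0.00179278
338,0.00245657
340,0.00333264
342,0.00447616
344,0.00595223
346,0.0078363
348,0.0102141
350,0.0131809
352,0.0168402
354,0.0213014
356,0.0266763
358,0.033075
360,0.0406005
362,0.0493424
364,0.0593701
366,0.0707249
368,0.0834134
370,0.0973995
372,0.1126
374,0.128877
376,0.146042
378,0.163847
380,0.181996
382,0.200147
384,0.217924
386,0.234927
388,0.250746
390,0.264984
392,0.277265
394,0.28726
396,0.294698
398,0.299382
400,0.301198
402,0.300127
404,0.296242
406,0.289712
408,0.280796
410,0.26983
412,0.257221
414,0.243429
416,0.228949
418,0.214304
420,0.200018
422,0.186613
424,0.174588
426,0.164414
428,0.156527
430,0.151319
432,0.149137
434,0.150281
436,0.155001
438,0.163501
440,0.175933
442,0.192397
444,0.212943
446,0.237562
448,0.266188
450,0.298687
452,0.33486
454,0.374434
456,0.417057
458,0.462301
460,0.509659
462,0.558547
464,0.608312
466,0.658239
468,0.707562
470,0.755482
472,0.801183
474,0.843851
476,0.8827
478,0.916988
480,0.946042
482,0.969282
484,0.986233
486,0.996544
488,1
490,0.996527
492,0.986196
494,0.96922
496,0.945945
498,0.91684
500,0.882481
502,0.843533
504,0.800723
506,0.754826
508,0.706635
510,0.656943
512,0.606519
514,0.55609
516,0.506326
518,0.457825
520,0.411105
522,0.366597
524,0.324646
526,0.285506
528,0.249348
530,0.216261
532,0.186267
534,0.159323
536,0.135333
538,0.11416
540,0.0956327
542,0.079558
544,0.0657273
546,0.0539252
548,0.0439361
550,0.0355497
552,0.028565
554,0.0227938
556,0.0180627
558,0.0142145
560,0.0111088
562,0.00862154
564,0.00664489
566,0.00508597
568,0.00386585
570,0.00291809
572,0.00218745
574,0.0016284
576,0.00120384
578,0.00088381
580,0.000644368
582,0.000466544
584,0.000335456
586,0.000239532
588,0.000169853
590,0.000119611
592,8.36468e-05
594,5.80915e-05
596,4.00645e-05
598,2.74405e-05
600,1.86641e-05
602,1.26069e-05
604,8.45651e-06
606,5.63325e-06
608,3.72658e-06
610,2.4482e-06
612,1.59723e-06
614,1.03483e-06
616,0
618,0
620,0
622,0
624,0
626,0
628,0
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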