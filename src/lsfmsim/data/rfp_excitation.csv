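wavelength_nm,value
300,0
302,1.29686e-06
304,1.79788e-06
306,2.48142e-06
308,3.40965e-06
310,4.66433e-06
312,6.3524e-06
314,8.61304e-06
316,1.16264e-05
318,1.56244e-05
320,2.09041e-05
322,2.78438e-05
324,3.69229e-05
326,4.87454e-05
328,6.40679e-05
330,8.38335e-05
332,0.000109211
334,0.000141638
336,0.00018288
338,0.000235084
340,0.00030085
342,0.000383306
344,0.000486195
346,0.000613969
348,0.000771883
350,0.00096611
352,0.00120385
354,0.00149343
356,0.00184446
358,0.0022679
360,0.00277618
362,0.00338331
364,0.00410493
366,0.00495837
368,0.00596269
370,0.00713864
372,0.0085086
374,0.0100965
376,0.0119276
378,0.0140283
380,0.0164258
382,0.0191478
384,0.0222219
386,0.0256751
388,0.0295334
390,0.0338209
392,0.038559
394,0.0437659
396,0.0494557
398,0.0556374
400,0.0623142
402,0.0694827
404,0.0771323
406,0.0852444
408,0.0937918
410,0.102739
412,0.11204
414,0.121641
416,0.13148
418,0.141484
420,0.151575
422,0.161664
424,0.171661
426,0.181468
428,0.190984
430,0.200108
432,0.208738
434,0.216774
436,0.224122
438,0.230691
440,0.2364
442,0.241176
444,0.244957
446,0.247695
448,0.249353
450,0.24991
452,0.249359
454,0.247707
456,0.244977
458,0.241207
460,0.236448
462,0.230764
464,0.22423
466,0.216933
468,0.20897
470,0.200443
472,0.191464
474,0.18215
476,0.172623
478,0.163009
480,0.153438
482,0.144045
484,0.134972
486,0.126362
488,0.11837
490,0.111158
492,0.104897
494,0.0997708
496,0.0959782
498,0.0937314
500,0.0932577
502,0.0947992
504,0.0986105
506,0.104956
508,0.114104
510,0.126321
512,0.141861
514,0.160959
516,0.183811
518,0.21057
520,0.241321
522,0.276077
524,0.314753
526,0.357164
528,0.403009
530,0.451863
532,0.503179
534,0.556287
536,0.610403
538,0.664644
540,0.718047
542,0.769592
544,0.818235
546,0.862939
548,0.902709
550,0.93663
552,0.963896
554,0.983844
556,0.995981
558,1
560,0.995795
562,0.983465
564,0.963307
566,0.935805
568,0.901615
570,0.861529
572,0.816454
574,0.767373
576,0.715308
578,0.661289
580,0.606319
582,0.551344
584,0.497228
586,0.444733
588,0.394507
590,0.347073
592,0.302829
594,0.262051
596,0.224897
598,0.191423
600,0.16159
602,0.135284
604,0.112328
606,0.0925001
608,0.0755451
610,0.0611901
612,0.049155
614,0.0391619
616,0.0309436
618,0.0242488
620,0.018846
622,0.0145264
624,0.0111048
626,0.00841919
628,0.00633056
630,0.00472091
632,0.00349156
634,0.00256108
636,0.00186311
638,0.0013442
640,0.000961839
642,0.000682574
644,0.000480406
646,0.000335334
648,0.000232144
650,0.000159386
652,0.00010853
654,7.32931e-05
656,4.90892e-05
658,3.26077e-05
660,2.14815e-05
662,1.40353e-05
664,9.09468e-06
666,5.84473e-06
668,3.72523e-06
670,2.35479e-06
672,1.47625e-06
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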