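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
378,0
380,0
382,0
384,0
386,0
388,0
390,0
392,0
394,0
396,0
398,0
400,0
402,0
404,0
406,0
408,0
410,0
412,0
414,0
416,0
418,0
420,0
422,0
424,0
426,0
428,0
430,0
432,0
434,0
436,0
438,0
440,0
442,0
444,0
446,0
448,0
450,0
452,1.29212e-06
454,1.71104e-06
456,2.25839e-06
458,2.97113e-06
460,3.89607e-06
462,5.09232e-06
464,6.63421e-06
466,8.61487e-06
468,1.11505e-05
470,1.43858e-05
472,1.84999e-05
474,2.3714e-05
476,3.03008e-05
478,3.85948e-05
480,4.9006e-05
482,6.20357e-05
484,7.82968e-05
486,9.85386e-05
488,0.000123679
490,0.000154847
492,0.000193437
494,0.00024119
496,0.000300292
498,0.000373529
500,0.000464487
502,0.000577846
504,0.000719782
506,0.000898524
508,0.00112512
510,0.00141446
512,0.00178666
514,0.0022688
516,0.00289725
518,0.00372041
520,0.00480219
522,0.00622601
524,0.00809935
526,0.0105588
528,0.0137749
530,0.0179577
532,0.02336
534,0.0302809
536,0.0390659
538,0.0501045
540,0.0638236
542,0.0806764
544,0.101126
546,0.125621
548,0.154572
550,0.188315
552,0.227078
554,0.270941
556,0.319807
558,0.373364
560,0.431067
562,0.492125
564,0.555506
566,0.619954
568,0.684027
570,0.746149
572,0.804678
574,0.857982
576,0.904524
578,0.942942
580,0.972128
582,0.991291
584,1
586,0.998211
588,0.986265
590,0.964868
592,0.935039
594,0.898057
596,0.855376
598,0.808548
600,0.75914
602,0.708654
604,0.658466
606,0.609767
608,0.563534
610,0.520505
612,0.481181
614,0.445835
616,0.414535
618,0.387177
620,0.363519
622,0.343218
624,0.325866
626,0.311023
628,0.298245
630,0.287104
632,0.277207
634,0.268206
636,0.259803
638,0.251752
640,0.24386
642,0.235982
644,0.228014
646,0.219891
648,0.21158
650,0.20307
652,0.194373
654,0.185516
656,0.176535
658,0.167475
660,0.158385
662,0.149314
664,0.140313
666,0.131431
668,0.122713
670,0.114203
672,0.105938
674,0.097951
676,0.0902718
678,0.0829237
680,0.0759256
682,0.0692915
684,0.0630311
686,0.0571493
688,0.0516475
690,0.0465233
692,0.0417708
694,0.0373815
696,0.0333444
698,0.0296464
700,0.0262725
702,0.0232067
704,0.0204319
706,0.0179301
708,0.0156834
710,0.0136735
712,0.0118824
714,0.0102921
716,0.00888569
718,0.00764642
720,0.00655854
722,0.0056071
724,0.00477806
726,0.00405832
728,0.00343576
730,0.00289922
732,0.00243849
734,0.0020443
736,0.00170824
738,0.00142277
740,0.00118114
742,0.000977355
744,0.000806092
746,0.000662671
748,0.000542992
750,0.000443477
752,0.00036102
754,0.000292935
756,0.000236916
758,0.000190985
760,0.000153457
762,0.000122901
764,9.81086e-05
766,7.8062e-05
768,6.19091e-05
770,4.89385e-05
772,3.85593e-05
774,3.02823e-05
776,2.37045e-05
778,1.84951e-05
780,1.43834e-05
782,1.11493e-05
784,8.61428e-06
786,6.63393e-06
788,5.09219e-06
790,3.89601e-06
792,2.9711e-06
794,2.25838e-06
796,1.71103e-06
798,1.29211e-06
800,0
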