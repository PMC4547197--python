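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
396,1.31038e-06
398,1.82068e-06
400,2.51851e-06
402,3.46837e-06
404,4.75536e-06
406,6.49113e-06
408,8.82145e-06
410,1.19358e-05
412,1.60792e-05
414,2.15673e-05
416,2.88052e-05
418,3.83111e-05
420,5.07467e-05
422,6.69559e-05
424,8.80163e-05
426,0.000115308
428,0.000150609
430,0.000196225
432,0.000255183
434,0.000331499
436,0.000430582
438,0.000559802
440,0.000729327
442,0.000953302
444,0.00125151
446,0.00165166
448,0.00219248
450,0.00292771
452,0.00393129
454,0.00530369
456,0.0071794
458,0.00973541
460,0.0132002
462,0.0178626
464,0.0240794
466,0.0322797
468,0.0429657
470,0.0567065
472,0.0741229
474,0.0958638
476,0.12257
478,0.154826
480,0.193107
482,0.237715
484,0.28871
486,0.345853
488,0.40856
490,0.475862
492,0.546411
494,0.618498
496,0.69012
498,0.759069
500,0.823052
502,0.879829
504,0.927367
506,0.963969
508,0.988407
510,1
512,0.998669
514,0.984932
516,0.959862
518,0.924997
520,0.882224
522,0.833635
524,0.781385
526,0.727552
528,0.674021
530,0.62239
532,0.573912
534,0.52947
536,0.489582
538,0.454434
540,0.423928
542,0.397743
544,0.375404
546,0.356339
548,0.339941
550,0.325612
552,0.312794
554,0.301001
556,0.289823
558,0.278938
560,0.268104
562,0.257157
564,0.245998
566,0.234586
568,0.22292
570,0.211037
572,0.198995
574,0.186868
576,0.174742
578,0.162701
580,0.150834
582,0.139222
584,0.127939
586,0.117052
588,0.106618
590,0.0966854
592,0.0872895
594,0.0784575
596,0.0702067
598,0.0625449
600,0.0554723
602,0.0489813
604,0.0430581
606,0.0376833
608,0.0328331
610,0.0284804
612,0.0245952
614,0.0211457
616,0.0180995
618,0.0154234
620,0.0130846
622,0.0110513
624,0.00929258
626,0.00777908
628,0.00648321
630,0.00537925
632,0.00444348
634,0.00365422
636,0.00299182
638,0.00243863
640,0.00197892
642,0.00159874
644,0.00128587
646,0.00102965
648,0.000820821
650,0.000651445
652,0.000514728
654,0.000404899
656,0.000317093
658,0.000247226
660,0.000191899
662,0.000148294
664,0.000114088
666,8.73834e-05
668,6.66326e-05
670,5.05841e-05
672,3.82307e-05
674,2.8766e-05
676,2.15485e-05
678,1.60703e-05
680,1.19316e-05
682,8.81956e-06
684,6.49027e-06
686,4.75499e-06
688,3.46821e-06
690,2.51844e-06
692,1.82065e-06
694,1.31036e-06
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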