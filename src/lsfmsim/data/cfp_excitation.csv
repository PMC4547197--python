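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
330,1.03615e-06
332,1.74283e-06
334,2.90232e-06
336,4.78512e-06
338,7.81082e-06
340,1.26229e-05
342,2.01965e-05
344,3.19928e-05
346,5.01747e-05
348,7.79066e-05
350,0.000119762
352,0.000182274
354,0.000274654
356,0.000409735
358,0.000605171
360,0.000884932
362,0.00128115
364,0.0018363
366,0.00260584
368,0.00366107
370,0.00509243
372,0.00701293
374,0.0095616
376,0.0129068
378,0.017249
380,0.0228227
382,0.0298969
384,0.0387742
386,0.0497871
388,0.0632918
390,0.079659
392,0.0992613
394,0.122456
396,0.149569
398,0.180866
400,0.216536
402,0.256661
404,0.301194
406,0.349938
408,0.402524
410,0.458406
412,0.516851
414,0.57695
416,0.637628
418,0.697676
420,0.755784
422,0.810584
424,0.860708
426,0.904837
428,0.941765
430,0.970446
432,0.99005
434,1
436,1
438,0.99005
440,0.970446
442,0.941765
444,0.904837
446,0.860708
448,0.810584
450,0.755784
452,0.697676
454,0.637628
456,0.57695
458,0.516851
460,0.458406
462,0.402524
464,0.349938
466,0.301194
468,0.256661
470,0.216536
472,0.180866
474,0.149569
476,0.122456
478,0.0992613
480,0.079659
482,0.0632918
484,0.0497871
486,0.0387742
488,0.0298969
490,0.0228227
492,0.017249
494,0.0129068
496,0.0095616
498,0.00701293
500,0.00509243
502,0.00366107
504,0.00260584
506,0.0018363
508,0.00128115
510,0.000884932
512,0.000605171
514,0.000409735
516,0.000274654
518,0.000182274
520,0.000119762
522,7.79066e-05
524,5.01747e-05
526,3.19928e-05
528,2.01965e-05
530,1.26229e-05
532,7.81082e-06
534,4.78512e-06
536,2.90232e-06
538,1.74283e-06
540,1.03615e-06
542,0
544,0
546,0
548,0
550,0
552,0
554,0
556,0
558,0
560,0
562,0
564,0
566,0
568,0
570,0
572,0
574,0
576,0
578,0
580,0
582,0
584,0
586,0
588,0
590,0
592,0
594,0
596,0
598,0
600,0
602,0
604,0
606,0
608,0
610,0
612,0
614,0
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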