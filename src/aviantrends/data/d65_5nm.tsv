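# CIE standard daylight illuminant D65, relative spectral power
# (normalized to 100 at 560 nm), 300-700 nm at 5 nm steps
300	0.0341
305	1.6643
310	3.2945
315	11.7652
320	20.2360
325	28.6447
330	37.0535
335	38.5011
340	39.9488
345	42.4302
350	44.9117
355	45.7750
360	46.6383
365	49.3637
370	52.0891
375	51.0323
380	49.9755
385	52.3118
390	54.6482
395	68.7015
400	82.7549
405	87.1204
410	91.4860
415	92.4589
420	93.4318
425	90.0570
430	86.6823
435	95.7736
440	104.8650
445	110.9360
450	117.0080
455	117.4100
460	117.8120
465	116.3360
470	114.8610
475	115.3920
480	115.9230
485	112.3670
490	108.8110
495	109.0820
500	109.3540
505	108.5780
510	107.8020
515	106.2960
520	104.7900
525	106.2390
530	107.6890
535	106.0470
540	104.4050
545	104.2250
550	104.0460
555	102.0230
560	100.0000
565	98.1671
570	96.3342
575	96.0611
580	95.7880
585	92.2368
590	88.6856
595	89.3459
600	90.0062
605	89.8026
610	89.5991
615	88.6489
620	87.6987
625	85.4936
630	83.2886
635	83.4939
640	83.6992
645	81.8630
650	80.0268
655	80.1207
660	80.2146
665	81.2462
670	82.2778
675	80.2810
680	78.2842
685	74.0027
690	69.7213
695	70.6652
700	71.6091
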