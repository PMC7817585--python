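symbol	type	start	end	strand
MT-DLoop	control	16024	16569	heavy
MT-DLoop	control	1	576	heavy
MT-TF	tRNA	577	647	heavy
MT-RNR1	rRNA	648	1601	heavy
MT-TV	tRNA	1602	1670	heavy
MT-RNR2	rRNA	1671	3229	heavy
MT-TL1	tRNA	3230	3304	heavy
MT-ND1	protein	3307	4262	heavy
MT-TI	tRNA	4263	4331	heavy
MT-TQ	tRNA	4329	4400	light
MT-TM	tRNA	4402	4469	heavy
MT-ND2	protein	4470	5511	heavy
MT-TW	tRNA	5512	5579	heavy
MT-TA	tRNA	5587	5655	light
MT-TN	tRNA	5657	5729	light
MT-TC	tRNA	5761	5826	light
MT-TY	tRNA	5826	5891	light
MT-COI	protein	5904	7445	heavy
MT-TS1	tRNA	7446	7514	light
MT-TD	tRNA	7518	7585	heavy
MT-COII	protein	7586	8269	heavy
MT-TK	tRNA	8295	8364	heavy
MT-ATP8	protein	8366	8572	heavy
MT-ATP6	protein	8527	9207	heavy
MT-COIII	protein	9207	9990	heavy
MT-TG	tRNA	9991	10058	heavy
MT-ND3	protein	10059	10404	heavy
MT-TR	tRNA	10405	10469	heavy
MT-ND4L	protein	10470	10766	heavy
MT-ND4	protein	10760	12137	heavy
MT-TH	tRNA	12138	12206	heavy
MT-TS2	tRNA	12207	12265	heavy
MT-TL2	tRNA	12266	12336	heavy
MT-ND5	protein	12337	14148	heavy
MT-ND6	protein	14149	14673	light
MT-TE	tRNA	14674	14742	light
MT-CYB	protein	14747	15887	heavy
MT-TT	tRNA	15888	15953	heavy
MT-TP	tRNA	15956	16023	light
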