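family	T.aestivum|salt	T.aestivum|drought	H.vulgare|salt	H.vulgare|drought	A.thaliana|salt	A.thaliana|drought	Z.mays|salt	Z.mays|drought	O.sativa|salt	O.sativa|drought
miR156	0	0	1	1	1	0	1	1	1	1
miR157	0	0	0	0	0	1	0	0	0	0
miR159	0	1	0	1	1	0	1	1	1	0
miR160	1	1	0	0	0	0	1	1	0	1
miR164	1	0	1	0	0	0	1	0	0	0
miR165	0	0	0	0	1	0	0	0	0	0
miR166	0	1	1	1	0	0	1	1	0	1
miR167	0	0	0	0	1	1	1	1	0	1
miR168	0	0	0	1	1	1	1	1	0	1
miR169	1	1	1	1	1	0	0	1	0	0
miR171	0	0	1	0	1	1	1	0	0	1
miR172	1	1	0	1	0	0	0	0	0	1
miR319	0	0	0	0	1	0	1	0	1	1
miR393	0	0	0	1	1	1	0	0	0	1
miR394	0	0	0	0	1	0	0	0	1	0
miR395	1	1	0	0	0	0	0	0	0	1
miR396	1	0	0	0	1	1	0	1	0	1
miR397	0	0	0	0	0	0	0	0	0	1
miR398	0	0	0	0	0	0	0	1	0	0
miR408	0	0	1	0	0	1	0	1	0	1
miR444	1	0	0	1	0	0	0	0	0	0
miR528	0	0	0	0	0	0	0	0	1	0
miR529	1	0	0	0	0	0	0	0	0	1
miR530	0	0	0	0	0	0	0	0	1	0
miR535	1	0	0	0	0	0	0	0	0	0
miR845	0	0	0	0	0	0	0	0	0	1
miR894	0	0	0	0	0	0	0	1	0	0
miR1125	0	0	0	0	0	0	0	0	0	1
miR5048	0	0	0	1	0	0	0	0	0	0
miR5049	1	1	0	1	0	0	0	0	0	0
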