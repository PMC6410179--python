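Spud ID	Name	Amino Acid Number	MW	pI	Instability Index	Aliphatic Index	GRAVY
PGSC0003DMG400002093	LEA1-1	123	13,268.01	9.4	48	71.54	−0.715
PGSC0003DMG400011437	LEA1-2	96	10,361.49	9.22	28.3	38.85	−1.161
PGSC0003DMG400011438	LEA1-3	88	9261.33	9.22	17.2	30.34	−1.116
PGSC0003DMG400011439	LEA1-4	271	26,628	8.19	3.02	44.06	−0.589
PGSC0003DMG400001819	LEA1-5	104	11,515.89	5.94	29.76	65.96	−0.828
PGSC0003DMG400000066	LEA2-1	163	17,950.67	4.74	20.54	96.2	−0.153
PGSC0003DMG400002090	LEA2-2	191	22,310.06	9.47	31.39	102.88	0.103
PGSC0003DMG400002586	LEA2-3	267	29,063.08	10.27	36.24	83	−0.136
PGSC0003DMG400005073	LEA2-4	227	25,846.5	9.93	52.17	82.03	−0.292
PGSC0003DMG400005685	LEA2-5	221	25,174.21	9.06	35.71	103.62	−0.015
PGSC0003DMG400005783	LEA2-6	235	26,022.56	9.87	43.17	100.72	−0.039
PGSC0003DMG400000067	LEA2-7	175	19,281.12	4.57	33.54	101.83	−0.189
PGSC0003DMG400005898	LEA2-8	208	23,404.16	9.08	48.26	103.51	0.089
PGSC0003DMG400006460	LEA2-9	320	35,591.61	5.34	26.71	89.47	−0.463
PGSC0003DMG400008711	LEA2-10	270	29,709.53	9.77	45.43	87.63	−0.15
PGSC0003DMG400011296	LEA2-11	228	25,291.92	9.69	50.24	105.88	0.133
PGSC0003DMG400000069	LEA2-12	223	24,906.2	9.68	19.77	94.71	−0.111
PGSC0003DMG400012142	LEA2-13	197	21,631.87	9.1	35.79	85.53	0.197
PGSC0003DMG400013715	LEA2-14	320	35,609.51	4.83	24.23	96.19	−0.41
PGSC0003DMG400015214	LEA2-15	258	29,131.51	10.1	36.09	102.33	−0.092
PGSC0003DMG400016390	LEA2-16	229	26,053.18	8.97	43.15	77.42	−0.154
PGSC0003DMG400016420	LEA2-17	211	23,915.69	9.44	40.96	88.67	−0.132
PGSC0003DMG400000115	LEA2-18	198	21,541.04	9.69	20.03	85	0.171
PGSC0003DMG400018355	LEA2-19	224	25,280.38	8.72	49.75	87.95	−0.169
PGSC0003DMG400019407	LEA2-20	175	19,541.28	4.79	25.24	87.94	−0.362
PGSC0003DMG400019632	LEA2-21	257	28,453.37	10.19	46.62	72.18	−0.325
PGSC0003DMG400019639	LEA2-22	209	23,687.5	9.36	38.63	108.56	0.115
PGSC0003DMG400020863	LEA2-23	204	22,542.59	9.53	34.85	118.43	0.245
PGSC0003DMG400020886	LEA2-24	204	23,102.85	9.7	34.46	87.94	−0.19
PGSC0003DMG400021454	LEA2-25	259	29,397.61	10.06	40.41	92.12	−0.344
PGSC0003DMG400000476	LEA2-26	209	24,030.01	10.05	40.72	98.76	−0.191
PGSC0003DMG400024324	LEA2-27	193	22,002.62	9.83	36.55	103.52	−0.051
PGSC0003DMG400026335	LEA2-28	107	12,026.84	6.58	43.24	93.74	−0.077
PGSC0003DMG400028151	LEA2-29	211	24,106.86	9.59	52.84	91.8	−0.153
PGSC0003DMG400028152	LEA2-30	225	26,077.18	9.29	42.62	86.18	−0.279
PGSC0003DMG400028153	LEA2-31	230	26,121.29	9.11	46.83	89	−0.219
PGSC0003DMG400028235	LEA2-32	225	26,126.21	9.3	43.04	86.62	−0.318
PGSC0003DMG400029777	LEA2-33	227	24,670.78	9.41	28.14	105.15	0.257
PGSC0003DMG400000583	LEA2-34	213	23,996.84	9.41	31.45	90.56	−0.098
PGSC0003DMG400032803	LEA2-35	302	34,188.98	9.11	42.42	86.46	−0.198
PGSC0003DMG400037897	LEA2-36	235	26,782.17	9.59	51.48	95.7	−0.196
PGSC0003DMG401019715	LEA2-37	260	29,590.68	9.57	46.77	91.08	−0.217
PGSC0003DMG401021419	LEA2-38	192	21,050.61	9.53	25.77	100.05	0.177
PGSC0003DMG401027691	LEA2-39	214	24,317.33	9.55	40.92	92.94	−0.204
PGSC0003DMG402002623	LEA2-40	310	34,258.25	9.75	55.92	76.03	−0.324
PGSC0003DMG400012315	LEA2-41	197	22,684.33	10.42	52.16	90.56	−0.23
PGSC0003DMG400012355	LEA2-42	223	25,274	9.68	33.41	87.4	−0.217
PGSC0003DMG400042041	LEA2-43	101	11,316.65	10.02	18.01	107.03	0.242
PGSC0003DMG400002014	LEA2-44	263	29,204.88	9.97	43.83	87	−0.222
PGSC0003DMG400002082	LEA2-45	222	25,335.22	9.51	41.89	91.76	−0.106
PGSC0003DMG400004703	LEA3-1	97	10,887.16	9.2	41.7	57.22	−0.903
PGSC0003DMG400017936	LEA3-2	89	9786.03	9.66	45.73	66.85	−0.473
PGSC0003DMG400031788	LEA3-3	98	10,402.73	9.89	51.67	73.67	−0.351
Sotub08g019440.1.1	LEA3-4	84	9575.08	9.66	49.98	65	−0.554
PGSC0003DMG400002731	LEA4-1	400	43,122.45	5.46	26.56	51	−1.093
PGSC0003DMG400019976	LEA4-2	501	53,302.67	5.32	29.5	57.56	−0.816
PGSC0003DMG400029706	LEA4-3	255	28,437.98	8.84	39.03	47.61	−1.112
PGSC0003DMG400006648	LEA5-1	93	10,011.84	5.91	55.08	40.97	−1.446
PGSC0003DMG400008497	LEA5-2	100	10,855.84	9.1	60.31	38.1	−1.469
PGSC0003DMG400041241	LEA5-3	105	11,740.47	10.07	68.21	68.67	−1.017
PGSC0003DMG400024942	LEA6-1	88	9221.92	5.11	42.02	46.7	−1.125
PGSC0003DMG400003530	DHN-1	140	14,534.01	7.07	34.82	15.36	−1.268
PGSC0003DMG400003531	DHN-2	157	16,659.06	7.23	21.86	36.69	−1.214
PGSC0003DMG400009968	DHN-3	209	23,673.14	5.24	63.91	47.56	−1.499
PGSC0003DMG400015495	DHN-4	80	8544.27	5.9	29.91	37.88	−1.31
PGSC0003DMG400030949	DHN-5	243	25,121.94	7.38	23.94	59.92	−0.715
PGSC0003DMG400019328	SMP-1	257	26,335.96	4.47	40.16	80.54	−0.251
PGSC0003DMG400022470	SMP-2	206	21,737.03	6.78	48.15	74.03	−0.729
Sotub09g023980.1.1	SMP-3	259	26,563.44	4.7	41.15	74.09	−0.353
Sotub09g023990.1.1	SMP-4	263	25,839.64	4.62	35.47	73.57	−0.184
PGSC0003DMG400006661	ASR-1	306	33,956.66	4.92	28.91	19.87	−1.629
PGSC0003DMG400006662	ASR-2	109	12,370.74	6.57	40.22	54.86	−1.294
PGSC0003DMG400006663	ASR-3	111	12,481.95	9.25	41.47	52.97	−1.31
PGSC0003DMG400024093	ASR-4	108	12,158.49	6.65	46.37	52.59	−1.235
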