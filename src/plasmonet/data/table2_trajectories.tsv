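# Single-cell trajectories of significant gene-expression states.
# 24 Physarum polycephalum plasmodia (P1-P24), two experimental batches,
# dark controls vs far-red stimulated, sampled hourly from 0 h to 10 h.
experiment	condition	cell	t0	t1	t2	t3	t4	t5	t6	t7	t8	t9	t10
1	dark	P1	60	56	59	26	35	34	34	28	28	32	31
1	dark	P2	57	57	60	63	35	35	35	14	32	32	32
1	dark	P3	59	56	26	36	34	34	28	13	31	32	32
1	dark	P4	37	37	37	33	28	28	28	15	29	30	30
2	dark	P5	24	52	52	52	49	52	52	52	48	47	48
2	dark	P6	25	45	45	44	44	43	43	21	7	5	1
2	dark	P7	3	3	3	11	12	63	63	60	60	26	61
2	dark	P8	46	45	45	42	42	42	43	21	7	6	1
1	far_red	P9	33	23	27	16	101	111	105	87	88	70	79
1	far_red	P10	36	23	27	16	88	111	105	89	80	75	78
1	far_red	P11	10	53	54	54	15	98	100	89	91	93	71
1	far_red	P12	53	55	54	54	15	100	100	89	91	92	71
1	far_red	P13	8	4	4	12	53	69	69	68	66	65	95
1	far_red	P14	22	4	2	9	53	69	69	68	66	65	95
1	far_red	P15	22	4	2	9	96	96	69	67	64	94	95
1	far_red	P16	62	55	58	54	97	99	89	90	93	75	78
2	far_red	P17	50	40	45	19	104	103	105	87	82	72	79
2	far_red	P18	51	41	25	19	104	102	110	85	81	72	77
2	far_red	P19	20	20	20	17	18	102	109	83	82	72	77
2	far_red	P20	44	40	45	19	103	108	110	84	82	73	77
2	far_red	P21	51	39	45	19	103	106	110	84	82	74	76
2	far_red	P22	52	39	45	19	103	107	110	86	81	73	76
2	far_red	P23	46	39	45	19	103	107	110	86	81	73	77
2	far_red	P24	24	38	45	19	104	108	110	84	81	74	77
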