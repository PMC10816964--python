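table	endpoint	instrument	cutoff	label	n	n_pos	sens	spec	ppv	npv	lr_pos	lr_neg	odds_ratio	roc
2	AHI>=5	bamsa	5	BAMSA >= 5	160	70	11.4	98.9	88.9	58.9	10.3	0.896	11.5	0.552
2	AHI>=5	bamsa	4	BAMSA >= 4	160	70	57.1	86.7	76.9	72.2	4.29	0.495	8.67	0.719
2	AHI>=5	bamsa	3	BAMSA >= 3	160	70	78.6	52.2	56.1	75.8	1.64	0.41	4.01	0.654
2	AHI>=5	stopbang	4	STOP-BANG >= 4	160	70	65.7	63.3	58.2	70.4	1.79	0.541	3.31	0.645
2	AHI>=5	stopbang	3	STOP-BANG >= 3	160	70	80	46.7	53.8	75	1.5	0.429	3.5	0.633
2	AHI>=5	stopbang_new	4	STOP-BANGnew >= 4	160	70	60	74.4	64.6	70.5	2.35	0.537	4.37	0.672
2	AHI>=5	stopbang_new	3	STOP-BANGnew >= 3	160	70	77.1	53.3	56.3	75	1.65	0.429	3.86	0.652
2	AHI>=5	berlin	1	Berlin high risk	160	70	58.6	73.3	63.1	69.5	2.2	0.565	3.89	0.660
2	AHI>=5	nosas	7	NoSAS >= 7	160	70	85.7	34.4	50.4	75.6	1.31	0.415	3.15	0.601
2	AHI>=5	nosas	8	NoSAS >= 8	160	70	75.7	48.9	53.5	72.1	1.48	0.497	2.98	0.623
2	AHI>=5	nosas	9	NoSAS >= 9	160	70	70	53.3	53.8	69.6	1.5	0.563	2.67	0.617
2	AHI>=5	ess	16	ESS >= 16	160	70	8.57	97.8	75	57.9	3.86	0.935	4.13	0.532
2	AHI>=5	ess	11	ESS >= 11	160	70	31.4	72.2	46.8	57.5	1.13	0.949	1.19	0.518
2	AHI>=5	tiredness	3	Tiredness >= 1 day/week	160	70	87.1	20	45.9	66.7	1.09	0.643	1.69	0.536
3	AHI>=15	bamsa	5	BAMSA >= 5	160	28	17.9	97	55.6	84.8	5.89	0.847	6.96	0.574
3	AHI>=15	bamsa	4	BAMSA >= 4	160	28	85.7	78.8	46.2	96.3	4.04	0.181	22.3	0.823
3	AHI>=15	bamsa	3	BAMSA >= 3	160	28	100	47	28.6	100	1.89	0	undef	0.735
3	AHI>=15	stopbang	4	STOP-BANG >= 4	160	28	85.7	58.3	30.4	95.1	2.06	0.245	8.4	0.720
3	AHI>=15	stopbang	3	STOP-BANG >= 3	160	28	92.9	40.9	25	96.4	1.57	0.175	9	0.669
3	AHI>=15	stopbang_new	4	STOP-BANGnew >= 4	160	28	82.1	68.2	35.4	94.7	2.58	0.262	9.86	0.752
3	AHI>=15	stopbang_new	3	STOP-BANGnew >= 3	160	28	92.9	47	27.1	96.9	1.75	0.152	11.5	0.699
3	AHI>=15	berlin	1	Berlin high risk	160	28	78.6	67.4	33.8	93.7	2.41	0.318	7.59	0.730
3	AHI>=15	nosas	7	NoSAS >= 7	160	28	92.9	29.5	21.8	95.1	1.32	0.242	5.45	0.612
3	AHI>=15	nosas	8	NoSAS >= 8	160	28	89.3	43.9	25.3	95.1	1.59	0.244	6.53	0.666
3	AHI>=15	nosas	9	NoSAS >= 9	160	28	82.1	48.5	25.3	92.8	1.59	0.368	4.33	0.653
3	AHI>=15	ess	16	ESS >= 16	160	28	7.14	95.5	25	82.9	1.57	0.973	1.62	0.513
3	AHI>=15	ess	11	ESS >= 11	160	28	28.6	70.5	17	82.3	0.967	1.01	0.954	0.495
3	AHI>=15	tiredness	3	Tiredness >= 1 day/week	160	28	89.3	18.2	18.8	88.9	1.09	0.589	1.85	0.537
mwt	AHI>=5&MWT<19.4	bamsa	3	BAMSA >= 3 (AHI>=5 & MWT<19.4)	156	19	94.7	43.8						0.693
mwt	AHI>=5&MWT<19.4	bamsa	4	BAMSA >= 4 (AHI>=5 & MWT<19.4)	156	19	63.2	72.3						0.677
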