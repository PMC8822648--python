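osf	ode_name	ode_sf	ode_fish	ode_abundance	ode_rps	ode_divpeak	lmi_name	lmi_sf	lmi_fish	lmi_abundance	lmi_rps	lmi_divpeak	mal_bp	cei_ode	cei_lmi	interspecific_identity	interspecific_divergence	ctr_printed	ilibs_printed
1	OdeSat01-287	1	B	6.2e-03	0.87	1	LmiSat09-181	5	B	3.0e-04	0.65	0	4417	88.4	85.6	68.9	90.8	1.990	0.30
2	OdeSat02-204	4	B	3.3e-03	0.51	2	LmiSat03-195	6	B	3.0e-03	0.63	3	13447	124.5	125.1	60.6	130.4	2.858	0
3	OdeSat17-176	1	NS	2.0e-04	0.29	27	LmiSat02-176	1	B	3.6e-03	0.68	4	20180	-24.6	-5.1	99.4	0.6	0.013	1.00
4	OdeSat21-228	3	NS	1.5e-04	0.58	3	LmiSat51-241	1	B	2.9e-05	0.61	3	1708	67.0	66.5	71.8	72.8	1.596	0.44
4	OdeSat32-238	2	B	8.5e-05	0.36	2	LmiSat26-240	2	B	1.0e-04	0.60	3	1455	40.5	47.8	77.7	53.1	1.164	0.59
4	OdeSat32-238	2	B	8.5e-05	0.36	2	LmiSat37-238	1	B	4.6e-05	0.59	3	2454	54.4	59.5	75.6	67	1.469	0.49
5	OdeSat22-267	3	B	1.4e-04	0.59	1	LmiSat12-273	3	B	1.3e-04	0.74	1	2948	90.6	94.8	75	98.1	2.150	0.25
5	OdeSat22-267	3	B	1.4e-04	0.59	1	LmiSat16-278	1	B	1.4e-04	0.87	2	1965	89.5	94.6	72.6	97	2.126	0.26
6	OdeSat26-180	1	B	1.3e-04	0.88	2	LmiSat41-180	1	B	5.1e-05	0.94	3	515	29.2	28.2	74.4	31.7	0.695	0.76
7	OdeSat28-276	1	B	1.2e-04	0.56	5	LmiSat24-266	1	NS	5.9e-05	0.90	0	1378	49.4	53.4	67.9	55.8	1.223	0.57
7	OdeSat28-276	1	B	1.2e-04	0.56	5	LmiSat45-274	1	B	2.5e-05	0.54	2	945	19.0	16.8	79.7	25.4	0.557	0.81
7	OdeSat28-276	1	B	1.2e-04	0.56	5	LmiSat54-272	1	B	1.6e-05	0.65	0	2073	58.7	60.2	66.3	65.1	1.427	0.50
7	OdeSat58-265	2	NS	9.5e-06	0.88	0	LmiSat28-263	2	B	6.0e-05	0.97	0	2821	30.1	32.4	77.5	33.9	0.743	0.74
7	OdeSat58-265	2	NS	9.5e-06	0.88	0	LmiSat43-231	1	B	3.9e-05	1.00	0		39.3	42.7	69.3	43.1	0.945	0.67
8	OdeSat39-185	2	NS	6.8e-05	0.67	4	LmiSat06-185	4	B	4.9e-04	0.66	3	19168	14.9	16.1	84.3	21	0.460	0.84
9	OdeSat41-75	1	NS	6.1e-05	0.29	18	LmiSat27-57	1	NS	5.4e-05	0.32	0	712	-2.4	7.1	92.7	16.2	0.355	0.88
10	OdeSat56-249	1	NS	2.0e-05	0.93	0	LmiSat32-261	1	B	3.9e-05	0.60	0	1489	31.5	26.4	77.2	32.9	0.721	0.75
11	OdeSat57-75	1	NS	1.4e-05	0.40	4	LmiSat17-75	1	B	1.2e-04	0.48	2	3194	-1.3	2.7	92	8.5	0.186	0.93
12	OdeSat59-185	1	NS	5.8e-06	0.36	3	LmiSat01-185	5	B	9.8e-03	0.46	3	17619	-0.9	7.2	98.9	11.8	0.259	0.91
12	OdeSat59-185	1	NS	5.8e-06	0.36	3	LmiSat13-259	5	B	1.5e-04	0.76	4	1379	44.1	52.3	63.3	56.8	1.245	0.56
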