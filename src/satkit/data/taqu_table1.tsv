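name	genome_proportion	monomer_length	at_percent	mean_k2p	tsi	divpeak	rsp
TaquSat1-183	0.55864	183	67.2	12.85	0.85	10	0.36
TaquSat2-107	0.16776	107	55.1	13.63	0.93	13	0.56
TaquSat3-6	0.12463	6	66.7	15.61	0.76	24	0.21
TaquSat4-437	0.08	437	30.4	13.3	0.83	12	0.44
TaquSat4-466	0.066	466	32.6	18.5	0.84	19	0.42
TaquSat5-3102	0.04003	3102	53	0.14	0.99	0	1.00
TaquSat6-84	0.04000	84	65.5	20.63	0.53	21	0.28
TaquSat7-60	0.00993	60	48.3	16.72	0.41	17	0.28
TaquSat8-45	0.00532	45	51.1	3.01	0.45	2	0.81
TaquSat9-90	0.00425	90	56.7	16.28	0.40	14	0.34
TaquSat10-24	0.00418	24	50	18.16	0.48	15	0.48
TaquSat11-71	0.00233	71	40.3	2.1	0.09	1	0.98
TaquSat12-101	0.00180	101	50.5	7.73	0.01	6	0.43
TaquSat13-54	0.00175	54	59.3	18.7	0.20	24	0.24
TaquSat14-17	0.00129	17	35.3	21.69	0.36	18	0.33
TaquSat15-64	0.00045	64	45.3	4.89	0.00	8	0.38
Telomeric	0.13160	6	50	18.29	0.91	18	0.57
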