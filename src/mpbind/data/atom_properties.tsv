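element	mass	vdw_radius	electronegativity	covalent_radius	polarizability	hb_donor	hb_acceptor
C	12.011	1.70	2.55	0.76	1.76	0.0	0.0
N	14.007	1.55	3.04	0.71	1.10	1.0	1.0
O	15.999	1.52	3.44	0.66	0.80	1.0	1.0
S	32.06	1.80	2.58	1.05	2.90	0.5	0.5
P	30.974	1.80	2.19	1.07	3.63	0.0	0.0
SE	78.971	1.90	2.55	1.20	3.77	0.5	0.5
F	18.998	1.47	3.98	0.57	0.56	0.0	1.0
CL	35.45	1.75	3.16	1.02	2.18	0.0	1.0
BR	79.904	1.85	2.96	1.20	3.05	0.0	1.0
I	126.904	1.98	2.66	1.39	5.35	0.0	1.0
X	40.0	1.80	2.00	1.20	3.00	0.0	0.0
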