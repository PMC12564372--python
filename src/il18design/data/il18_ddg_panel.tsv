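variant	ddg_binding	ddg_fold_complex	ddg_fold_ligand	reported_score	group
WT	0	0	0	0	control
E6K	-1.9	-0.6	0.3	1.95	control
T63A	-0.8	0.8	0.8	-0.44	control
M60Q	4.6	2.2	0.8	-5.35	control
M33Q	4.6	2.9	2.7	-7.02	control
E6M	-1.4	-1.7	-0.8	2.76	single
K129M	-3.0	-0.8	-0.1	2.74	single
R131K	-3.0	0.2	0.0	1.93	single
N111S	-1.2	-1.1	-0.3	1.87	single
R131G	-0.6	-0.9	-1.1	1.70	single
K129M+R131G	-2.0	-2.5	-2.1	4.48	double
E6M+R131G	-1.9	-2.6	-1.9	4.43	double
E6M+K129M	-2.3	-2.6	-0.9	4.02	double
E6M+N111S	-2.0	-2.6	-1.1	3.98	double
E6M+R131K	-3.4	-1.5	-0.7	3.94	double
N111S+R131G	-2.2	-1.9	-1.4	3.82	double
R131K+N111S	-4.0	-0.9	-0.2	3.63	double
K129M+N111S	-2.6	-2.0	-0.4	3.52	double
K129M+R131K	-2.4	-0.6	0.0	2.09	double
E6M+K129M+R131G+N111S	-5.4	-5.6	-3.2	9.78	multiple
E6M+N111S+R131G	-4.8	-4.0	-2.2	7.66	multiple
E6M+K129M+R131G	-3.7	-4.3	-2.9	7.45	multiple
K129M+N111S+R131G	-4.7	-3.8	-2.3	7.45	multiple
E6M+K129M+R131K+N111S	-4.8	-3.1	-1.1	6.35	multiple
E6M+R131K+N111S	-4.2	-2.3	-1.0	5.27	multiple
E6M+K129M+N111S	-2.3	-3.5	-1.2	4.88	multiple
E6M+K129M+R131K	-3.5	-2.3	-0.8	4.65	multiple
K129M+R131K+N111S	-3.9	-1.7	-0.3	4.13	multiple
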