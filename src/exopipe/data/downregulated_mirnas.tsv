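mirna	mean_dct_end	mean_dct_onset	mean_rq_end	mean_rq_onset	fold_change	p_adj
hsa-miR-376a	3.28	1.28	0.10	0.41	-2.0	5.30E-08
hsa-miR-150	-6.04	-7.60	65.87	194.19	-1.6	9.87E-08
hsa-miR-376c	2.69	0.70	0.16	0.62	-2.0	1.48E-07
hsa-miR-132	1.33	-0.55	0.40	1.47	-1.9	5.45E-07
hsa-miR-130a	1.36	-0.49	0.39	1.40	-1.8	1.21E-05
hsa-miR-539	2.61	0.85	0.16	0.55	-1.8	3.22E-05
hsa-miR-342-3p	-2.59	-3.70	6.03	12.96	-1.1	4.81E-05
hsa-miR-192	1.40	0.06	0.38	0.96	-1.3	5.95E-05
hsa-miR-340	3.02	1.78	0.12	0.29	-1.2	5.95E-05
hsa-miR-320	-4.01	-4.97	16.10	31.28	-1.0	7.29E-05
hsa-let-7g	0.24	-1.06	0.85	2.08	-1.3	9.93E-05
hsa-miR-590-5p	0.96	-0.30	0.51	1.23	-1.3	9.93E-05
hsa-miR-152	2.44	1.22	0.18	0.43	-1.2	2.27E-04
hsa-miR-146b	-3.45	-4.37	10.91	20.74	-0.9	2.27E-04
hsa-miR-20a	-3.86	-5.32	14.56	39.97	-1.5	3.64E-04
hsa-miR-25	-0.31	-1.69	1.24	3.23	-1.4	3.64E-04
hsa-miR-26b	0.19	-1.15	0.88	2.22	-1.3	3.64E-04
hsa-miR-324-3p	1.73	0.62	0.30	0.65	-1.1	4.52E-04
hsa-miR-199a-3p	-0.01	-1.41	1.01	2.65	-1.4	4.95E-04
hsa-miR-106b	-0.59	-1.75	1.50	3.36	-1.2	5.83E-04
hsa-miR-19b	-4.65	-6.15	25.11	71.00	-1.5	6.23E-04
hsa-miR-374	-1.50	-2.61	2.82	6.11	-1.1	6.54E-04
hsa-miR-29c	2.42	1.03	0.19	0.49	-1.4	9.50E-04
hsa-miR-20b	-1.84	-2.92	3.57	7.55	-1.1	1.03E-03
hsa-miR-26a	-1.83	-3.01	3.57	8.07	-1.2	1.09E-03
hsa-miR-140-3p	3.24	2.38	0.11	0.19	-0.9	1.65E-03
hsa-miR-18a	1.47	0.31	0.36	0.80	-1.2	1.65E-03
hsa-miR-185	1.08	-0.04	0.47	1.03	-1.1	1.65E-03
hsa-miR-195	-0.71	-1.81	1.63	3.50	-1.1	1.69E-03
hsa-miR-142-3p	-2.80	-4.16	6.95	17.86	-1.4	2.02E-03
hsa-miR-21	-1.44	-2.66	2.72	6.31	-1.2	2.30E-03
hsa-miR-652	1.07	-0.15	0.47	1.11	-1.2	2.41E-03
hsa-miR-19a	-0.08	-1.40	1.06	2.65	-1.3	2.43E-03
hsa-let-7e	-2.27	-3.31	4.81	9.94	-1.0	2.55E-03
hsa-miR-106a	-5.59	-6.46	48.08	88.20	-0.9	2.55E-03
hsa-miR-660	1.40	0.29	0.38	0.82	-1.1	2.99E-03
hsa-miR-598	1.94	0.64	0.26	0.64	-1.3	3.56E-03
hsa-let-7d	0.11	-0.81	0.93	1.75	-0.9	3.73E-03
hsa-miR-24	-4.99	-5.75	31.85	53.81	-0.8	5.38E-03
hsa-miR-17	-5.42	-6.41	42.81	85.03	-1.0	5.47E-03
hsa-miR-483-5p	-0.30	-1.11	1.23	2.16	-0.8	5.67E-03
hsa-miR-30b	-2.76	-3.76	6.78	13.54	-1.0	5.99E-03
hsa-miR-301	1.70	0.70	0.31	0.62	-1.0	6.28E-03
hsa-miR-186	-2.53	-3.38	5.79	10.40	-0.8	8.42E-03
hsa-miR-331	-1.40	-2.13	2.63	4.38	-0.7	8.98E-03
hsa-miR-27a	0.15	-0.82	0.90	1.76	-1.0	9.19E-03
hsa-miR-15b	-0.63	-1.60	1.55	3.04	-1.0	9.41E-03
hsa-miR-28	2.12	1.28	0.23	0.41	-0.8	1.14E-02
hsa-miR-345	0.70	0.05	0.61	0.96	-0.6	1.28E-02
hsa-miR-30c	-3.10	-4.03	8.59	16.32	-0.9	1.29E-02
hsa-miR-103	0.95	0.13	0.52	0.91	-0.8	1.30E-02
hsa-miR-193b	1.91	1.21	0.27	0.43	-0.7	1.34E-02
hsa-miR-29a	-0.84	-1.54	1.78	2.91	-0.7	1.64E-02
hsa-miR-99b	2.30	1.69	0.20	0.31	-0.6	1.64E-02
hsa-miR-328	0.69	-0.16	0.62	1.12	-0.9	1.80E-02
hsa-miR-744	0.24	-0.53	0.85	1.45	-0.8	2.78E-02
hsa-miR-425-5p	0.38	-0.23	0.77	1.18	-0.6	3.23E-02
hsa-miR-92a	-2.30	-3.03	4.94	8.15	-0.7	3.23E-02
hsa-miR-16	-5.99	-6.86	63.78	116.19	-0.9	3.25E-02
hsa-miR-142-5p	2.39	1.66	0.19	0.32	-0.7	3.38E-02
hsa-miR-221	0.16	-0.73	0.90	1.66	-0.9	4.11E-02
hsa-miR-146a	-5.33	-5.98	40.31	62.91	-0.6	4.30E-02
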