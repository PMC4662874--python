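	g1_0	g1_1	g1_2	g2_0	g2_1	g2_2
t00	-0.0287	-0.6617	1.7672	0.01	-0.3394	-0.2421
t01	-0.2631	-0.3357	-0.3152	-0.3073	0.4372	-0.6716
t02	-1.9997	-2.5493	0.0568	0.9918	-1.2737	-2.5974
t03	-1.6159	1.5145	1.7112	1.2865	-1.2785	0.6265
t04	-0.382	-0.3606	-0.2235	-0.3595	-0.2639	-0.3923
t05	-0.1057	0.0151	-0.7218	-0.3205	-0.3736	-0.4331
t06	-0.6108	1.3499	-1.2651	0.7665	-2.1701	-0.677
t07	0.056	0.3848	0.4819	0.5456	-0.3412	-0.4294
t08	1.3795	0.3442	-0.7257	-0.5852	-0.3742	1.0235
t09	0.1505	0.4275	-0.1374	0.1586	0.3947	-0.0778
t10	0.8438	-1.417	-0.813	-0.8508	-2.4959	0.9048
t11	-1.3924	-0.4945	0.3778	0.3141	0.7218	-0.7013
t12	-1.2836	-0.9214	-2.6162	-2.363	-2.2318	-1.8887
t13	0.7419	-2.4743	-1.175	2.9582	-1.121	1.5741
t14	-1.3839	-0.3255	-1.4078	-0.5197	1.1945	-2.5376
t15	1.1024	1.0035	0.5852	0.1568	0.9202	0.6177
t16	0.3777	0.0945	2.2165	-0.2563	-1.3096	0.3059
t17	0.5935	1.1225	0.8792	0.6571	1.1709	-0.0606
t18	-1.5415	-2.1207	-1.0368	-3.0296	1.0329	-0.6984
t19	-2.0057	-1.5683	-0.2912	0.2128	1.3261	2.2073
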