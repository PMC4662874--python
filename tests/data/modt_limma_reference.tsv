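lfc	t	p	padj	s2_post
t00	-0.5494333333333	-0.8225986683449	0.4436385747006	0.872280497114	0.669183559430
t01	 0.1241000000000	 0.3275627952274	0.7548867447964	0.872280497114	0.215300820606
t02	 0.5376333333333	 0.4760305024726	0.6516712062734	0.872280497114	1.913348454368
t03	-0.3251000000000	-0.2858494440365	0.7850524474023	0.872280497114	1.940217843448
t04	-0.0165333333333	-0.0617960803096	0.9528256835096	0.971959413540	0.107371802724
t05	-0.1049333333333	-0.3223945127236	0.7585997166151	0.872280497114	0.158906958145
t06	-0.5182000000000	-0.5176291242893	0.6240983112081	0.872280497114	1.503310423334
t07	-0.3825666666667	-0.9939335222663	0.3603876157373	0.872280497114	0.222223936473
t08	-0.3113000000000	-0.4381120439355	0.6773491271754	0.872280497114	0.757319458616
t09	 0.0116333333333	 0.0367140642858	0.9719594135401	0.971959413540	0.150603364956
t10	-0.3519000000000	-0.3415581265868	0.7448689126904	0.872280497114	1.592210732719
t11	 0.6145666666667	 1.0017715844455	0.3568952827004	0.872280497114	0.564536262540
t12	-0.5541000000000	-1.0697397675172	0.3277485198726	0.872280497114	0.402449393670
t13	 2.1062333333333	 1.6246925444104	0.1577203359128	0.872280497114	2.520936157190
t14	 0.4181333333333	 0.4244349704098	0.6867327546765	0.872280497114	1.455789294493
t15	-0.3321333333333	-0.9556315696254	0.3778480899587	0.872280497114	0.181190411190
t16	-1.3162333333333	-1.8002218011865	0.1242777701159	0.872280497114	0.801871901271
t17	-0.2759333333333	-0.6610144296296	0.5342804633242	0.872280497114	0.261383225969
t18	 0.6679666666667	 0.6353809057656	0.5497134487625	0.872280497114	1.657801473471
t19	 2.5371333333333	 3.6382281082285	0.0117838891094	0.235677782188	0.729454137243
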