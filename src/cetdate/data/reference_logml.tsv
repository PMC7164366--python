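data	model	log_ml	se	pr_printed
1g_20s	AR	-4176.387	0.026	0.993
1g_20s	IR	-4181.350	0.019	0.007
1g_20s	STR	-4194.797	0.016	0.000
1g_40s	AR	-4957.026	0.050	1.000
1g_40s	IR	-4973.258	0.040	0.000
1g_40s	STR	-5010.601	0.047	0.000
1g_85s	AR	-6239.864	0.059	1.000
1g_85s	IR	-6258.492	0.069	0.000
1g_85s	STR	-6322.348	0.043	0.000
5g_20s	AR	-22529.810	0.035	0.999
5g_20s	IR	-22536.580	0.030	0.001
5g_20s	STR	-22555.840	0.022	0.000
20g_20s	AR	-94729.470	0.043	0.998
20g_20s	IR	-94738.010	0.058	0.002
20g_20s	STR	-94838.540	0.038	0.000
20g_40s	AR	-110512.300	0.181	1.000
20g_40s	IR	-110530.800	0.218	0.000
20g_40s	STR	-110668.500	0.130	0.000
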