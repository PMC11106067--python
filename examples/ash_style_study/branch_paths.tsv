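branch_id	age_ma	range
N1	53.85885916	WNA
N1	51.41976377	WNA,ENA
N1	50.49047083	WNA,ENA,EU
N1	38.91714866	WNA,ENA
N1	36.42320485	WNA,ENA
N10	1.884957246	ENA
N10	0.6403656663	ENA
N11	36.42320485	WNA,ENA
N11	32.81769736	WNA,ENA
N12	32.81769736	WNA,ENA
N12	29.04626881	WNA,ENA,CA
N12	23.50189049	WNA,ENA,EU,CA
N12	23.19778751	WNA,ENA,EU,CA
N13	23.19778751	WNA
N13	23.07139856	WNA
N14	23.07139856	WNA
N14	14.96029259	WNA,ENA
N14	11.3428685	WNA,ENA
N15	32.81769736	WNA
N15	24.09087017	WNA,CA
N15	22.721695	WNA,ENA,CA
N15	17.19337357	WNA,ENA,EA,CA
N15	16.64185731	WNA,ENA,EA,CA
N16	16.64185731	ENA,EA,CA
N16	14.63966865	ENA,EA,CA
N17	14.63966865	ENA,EA,CA
N17	12.70280461	ENA,JP,EA,CA
N17	8.149396611	ENA,JP,EA,CA
N18	8.149396611	EA
N18	0.2755910103	EA
N19	16.64185731	WNA
N19	14.38943602	WNA,EU
N19	13.34034238	WNA,EU
N2	36.42320485	ENA
N2	35.79552986	ENA,JP
N2	33.5502328	ENA,JP
N20	13.34034238	WNA
N20	4.070595346	WNA
N21	13.34034238	EU
N21	11.18355827	EU
N22	11.18355827	EU
N22	5.85270328	ENA,EU
N22	5.428047008	ENA,EU
N23	5.428047008	EU
N23	4.574810863	EU
N24	4.574810863	EU
N24	1.069215742	EU
N25	1.069215742	EU
N25	0.4896753845	EU
N3	33.5502328	ENA,JP
N3	33.52226401	ENA,JP,CA
N3	32.45779187	WNA,ENA,JP,CA
N3	30.9713755	WNA,ENA,JP,CA
N4	30.9713755	WNA,ENA,CA
N4	30.9027366	WNA,ENA,EA,CA
N4	26.12694951	WNA,ENA,EA,CA
N5	26.12694951	WNA,ENA,EA
N5	16.52493012	WNA,ENA,EA
N6	33.5502328	ENA
N6	31.03402091	WNA,ENA
N6	29.81713269	WNA,ENA,EA
N6	27.59642356	WNA,ENA,EA,CA
N6	26.40084497	WNA,ENA,EA,CA
N7	26.40084497	WNA,EA,CA
N7	25.8651804	WNA,EA,CA
N8	25.8651804	CA
N8	4.929786968	ENA,CA
N8	2.737410677	ENA,CA
N9	2.737410677	ENA
N9	1.884957246	ENA
f1	53.85885916	WNA
f1	38.87389697	WNA
f13	23.07139856	WNA
f13	19.91352733	WNA,JP
f13	18.78959671	WNA,JP,EU
f13	17.76972121	WNA,JP,EU
f15	11.3428685	WNA
f15	8.045833305	WNA,EU
f15	7.323681032	WNA,EU
f23	4.574810863	EU
f23	2.415071121	EU
f3	16.52493012	ENA,EA
f3	14.72549073	ENA,JP,EA
f3	13.9584713	WNA,ENA,JP,EA
f3	8.289330955	WNA,ENA,JP
f3	7.051525883	WNA,ENA,JP
f4	26.12694951	CA
f4	12.29381664	CA
f5	30.9713755	JP
f5	19.18221776	JP
t10	1.884957246	ENA
t10	0	ENA
t11	25.8651804	WNA,EA
t11	23.34322504	WNA,ENA,EA
t11	16.30357457	WNA,ENA,EA,CA
t11	12.53778695	WNA,ENA,EU,EA,CA
t11	10.26951343	WNA,ENA,JP,EU,EA,CA
t11	0.4952374487	WNA,ENA,EU,EA,CA
t11	0	WNA,ENA,EU,EA,CA
t12	23.19778751	ENA,EU,CA
t12	12.68035766	ENA,EU,EA,CA
t12	0	ENA,EU,EA,CA
t14	11.3428685	ENA
t14	1.655074283	ENA,JP
t14	0	ENA,JP
t16	8.149396611	ENA,JP,CA
t16	5.636816975	WNA,ENA,JP,CA
t16	1.429101873	WNA,ENA,JP,EA,CA
t16	0	WNA,ENA,JP,EA,CA
t17	0.2755910103	EA
t17	0	EA
t18	0.2755910103	EA
t18	0	EA
t19	14.63966865	EA
t19	9.834348742	EU,EA
t19	0	EU,EA
t2	16.52493012	WNA
t2	1.442527416	WNA,ENA
t2	0	WNA,ENA
t20	4.070595346	WNA
t20	3.155042424	WNA,JP
t20	0.6624052507	WNA,ENA,JP
t20	0	WNA,ENA,JP
t21	4.070595346	WNA
t21	0	WNA
t22	11.18355827	EU
t22	0	EU
t24	1.069215742	EU
t24	0	EU
t25	0.4896753845	EU
t25	0	EU
t26	0.4896753845	EU
t26	0	EU
t27	5.428047008	ENA
t27	0	ENA
t6	26.40084497	ENA
t6	24.65342326	ENA,EU
t6	19.84252756	ENA,JP,EU
t6	6.368078808	WNA,ENA,JP,EU
t6	5.984135583	WNA,ENA,JP,EU,CA
t6	0.867653507	WNA,ENA,JP,EU,EA,CA
t6	0	WNA,ENA,JP,EU,EA,CA
t7	2.737410677	ENA,CA
t7	0	ENA,CA
t8	0.6403656663	ENA
t8	0	ENA
t9	0.6403656663	ENA
t9	0	ENA
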