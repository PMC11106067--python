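time_ma	type	scope	source_range	detail	branch_id
51.41976377	dispersal	adjacent	WNA	ENA	N1
50.49047083	dispersal	intercontinental	WNA+ENA	EU	N1
38.91714866	extinction	n/a	WNA+ENA+EU	EU	N1
35.79552986	dispersal	intercontinental	ENA	JP	N2
33.52226401	dispersal	adjacent	ENA+JP	CA	N3
32.45779187	dispersal	adjacent	ENA+JP+CA	WNA	N3
31.03402091	dispersal	adjacent	ENA	WNA	N6
30.9713755	vicariance	intercontinental	WNA+ENA+JP+CA	WNA+ENA+CA|JP	N3
30.9027366	dispersal	adjacent	WNA+ENA+CA	EA	N4
29.81713269	dispersal	intercontinental	WNA+ENA	EA	N6
29.04626881	dispersal	intercontinental	WNA+ENA	CA	N12
27.59642356	dispersal	adjacent	WNA+ENA+EA	CA	N6
26.40084497	vicariance	intercontinental	WNA+ENA+EA+CA	ENA|WNA+EA+CA	N6
26.12694951	vicariance	intercontinental	WNA+ENA+EA+CA	WNA+ENA+EA|CA	N4
25.8651804	vicariance	intercontinental	WNA+EA+CA	CA|WNA+EA	N7
24.65342326	dispersal	intercontinental	ENA	EU	t6
24.09087017	dispersal	intercontinental	WNA	CA	N15
23.50189049	dispersal	adjacent	WNA+ENA+CA	EU	N12
23.34322504	dispersal	adjacent	WNA+EA	ENA	t11
23.19778751	vicariance	intercontinental	WNA+ENA+EU+CA	ENA+EU+CA|WNA	N12
22.721695	dispersal	adjacent	WNA+CA	ENA	N15
19.91352733	dispersal	intercontinental	WNA	JP	f13
19.84252756	dispersal	intercontinental	ENA+EU	JP	t6
18.78959671	dispersal	intercontinental	WNA+JP	EU	f13
17.19337357	dispersal	adjacent	WNA+ENA+CA	EA	N15
16.64185731	vicariance	intercontinental	WNA+ENA+EA+CA	ENA+EA+CA|WNA	N15
16.52493012	vicariance	intercontinental	WNA+ENA+EA	WNA|ENA+EA	N5
16.30357457	dispersal	adjacent	WNA+ENA+EA	CA	t11
14.96029259	dispersal	adjacent	WNA	ENA	N14
14.72549073	dispersal	adjacent	ENA+EA	JP	f3
14.38943602	dispersal	intercontinental	WNA	EU	N19
13.9584713	dispersal	adjacent	ENA+JP+EA	WNA	f3
13.34034238	vicariance	intercontinental	WNA+EU	WNA|EU	N19
12.70280461	dispersal	adjacent	ENA+EA+CA	JP	N17
12.68035766	dispersal	adjacent	ENA+EU+CA	EA	t12
12.53778695	dispersal	adjacent	WNA+ENA+EA+CA	EU	t11
11.3428685	vicariance	adjacent	WNA+ENA	ENA|WNA	N14
10.26951343	dispersal	adjacent	WNA+ENA+EU+EA+CA	JP	t11
9.834348742	dispersal	intercontinental	EA	EU	t19
8.289330955	extinction	n/a	WNA+ENA+JP+EA	EA	f3
8.149396611	vicariance	intercontinental	ENA+JP+EA+CA	ENA+JP+CA|EA	N17
8.045833305	dispersal	intercontinental	WNA	EU	f15
6.368078808	dispersal	adjacent	ENA+JP+EU	WNA	t6
5.984135583	dispersal	adjacent	WNA+ENA+JP+EU	CA	t6
5.85270328	dispersal	intercontinental	EU	ENA	N22
5.636816975	dispersal	adjacent	ENA+JP+CA	WNA	t16
5.428047008	vicariance	intercontinental	ENA+EU	EU|ENA	N22
4.929786968	dispersal	intercontinental	CA	ENA	N8
3.155042424	dispersal	intercontinental	WNA	JP	t20
1.655074283	dispersal	intercontinental	ENA	JP	t14
1.442527416	dispersal	adjacent	WNA	ENA	t2
1.429101873	dispersal	adjacent	WNA+ENA+JP+CA	EA	t16
0.867653507	dispersal	adjacent	WNA+ENA+JP+EU+CA	EA	t6
0.6624052507	dispersal	adjacent	WNA+JP	ENA	t20
0.4952374487	extinction	n/a	WNA+ENA+JP+EU+EA+CA	JP	t11
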