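node_id	range
N1	WNA
N10	ENA
N11	WNA,ENA
N12	WNA,ENA
N13	WNA
N14	WNA
N15	WNA
N16	ENA,EA,CA
N17	ENA,EA,CA
N18	EA
N19	WNA
N2	ENA
N20	WNA
N21	EU
N22	EU
N23	EU
N24	EU
N25	EU
N3	ENA,JP
N4	WNA,ENA,CA
N5	WNA,ENA,EA
N6	ENA
N7	WNA,EA,CA
N8	CA
N9	ENA
f1	WNA
f13	WNA
f15	WNA
f23	EU
f3	ENA,EA
f4	CA
f5	JP
t10	ENA
t11	WNA,EA
t12	ENA,EU,CA
t14	ENA
t16	ENA,JP,CA
t17	EA
t18	EA
t19	EA
t2	WNA
t20	WNA
t21	WNA
t22	EU
t24	EU
t25	EU
t26	EU
t27	ENA
t6	ENA
t7	ENA,CA
t8	ENA
t9	ENA
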