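tip	range
f1	WNA
f13	WNA,JP,EU
f15	WNA,EU
f23	EU
f3	WNA,ENA,JP
f4	CA
f5	JP
t10	ENA
t11	WNA,ENA,EU,EA,CA
t12	ENA,EU,EA,CA
t14	ENA,JP
t16	WNA,ENA,JP,EA,CA
t17	EA
t18	EA
t19	EU,EA
t2	WNA,ENA
t20	WNA,ENA,JP
t21	WNA
t22	EU
t24	EU
t25	EU
t26	EU
t27	ENA
t6	WNA,ENA,JP,EU,EA,CA
t7	ENA,CA
t8	ENA
t9	ENA
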