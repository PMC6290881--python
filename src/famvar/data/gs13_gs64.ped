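# Synthetic two-family fixture modelled on the published GS13/GS64 tallies:
# GS13: 4 affected (one a married-in spouse), 2 unaffected carriers,
#       3 unaffected non-carriers; founders and one spouse untyped.
# GS64: 4 affected (3 carriers, 1 non-carrier not exome-sequenced),
#       1 unaffected carrier, 4 unaffected non-carriers.
# Columns: family id father mother sex phenotype sequenced
GS13	f1	0	0	1	0	0
GS13	f2	0	0	2	0	0
GS13	a1	f1	f2	1	2	0
GS13	a2	f1	f2	2	2	1
GS13	u1	f1	f2	1	1	0
GS13	u2	f1	f2	2	1	0
GS13	s1	0	0	2	2	0
GS13	a3	a1	s1	1	2	1
GS13	u5	a1	s1	2	1	0
GS13	s2	0	0	1	0	0
GS13	u3	s2	a2	1	1	0
GS13	u4	s2	a2	2	1	0
GS64	g1	0	0	1	0	0
GS64	g2	0	0	2	0	0
GS64	b1	g1	g2	1	2	1
GS64	b2	g1	g2	2	2	0
GS64	v1	g1	g2	1	1	0
GS64	v2	g1	g2	2	1	0
GS64	t1	0	0	1	0	0
GS64	b3	t1	b2	1	2	1
GS64	b4	t1	b2	2	2	0
GS64	v3	t1	b2	1	1	0
GS64	v4	t1	b2	2	1	0
GS64	v5	t1	b2	1	1	0
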