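population	gene	ancestor	donor	recipient	recombinant	strong_selection
Ara+1	arcA	AA	GG	TT	GG	1
Ara+1	hslU	AA	GG	TT	GA	1
Ara+1	ycfC	AA	AA	TT	AA	0
Ara+1	yecE	AA	AA	TT	AA	0
Ara+4	infB	AA	AA	TT	AA	1
Ara+4	mreB	AA	AA	TT	AA	1
Ara+4	spoT	AA	GG	TT	GG	1
Ara+5	rplF	AA	AA	TT	AA	1
Ara+5	rpsC	AA	AA	TT	AA	0
Ara+5	yhdG	AA	AA	TT	AA	1
Ara-1	malT	AA	GG	TT	GG	1
Ara-1	rpsM	AA	AA	TT	AA	0
Ara-1	yghJ	AA	GG	TT	GA	0
Ara-3	fis	AA	AA	TT	AA	0
Ara-3	hslU	AA	AA	TT	AA	1
Ara-3	malT	AA	GG	TT	GG	1
Ara-3	mrdB	AA	AA	TT	AA	0
Ara-3	pykF	AA	AA	TT	AA	1
Ara-3	rpsG	AA	GG	TT	GG	0
Ara-3	tdcR	AA	AA	TT	AA	0
Ara-3	topA	AA	AA	TT	AA	1
Ara-4	garP	AA	AA	TT	AA	0
Ara-4	infA	AA	AA	TT	AA	0
Ara-4	mreB	AA	AA	TT	AA	1
Ara-4	nadR	AA	GG	TT	AA	1
Ara-4	pykF	AA	GG	TT	GA	1
Ara-4	spoT	AA	GG	TT	AA	1
Ara-4	ydfI	AA	GG	TT	AA	0
Ara-4	ypdC	AA	GG	TT	AA	0
Ara-5	ybaL	AA	AA	TT	AA	1
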