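pair_id	partner_a	partner_b	label	res_a	pos_a	res_b	pos_b	note
hzeta_homo	h14-3-3zeta	h14-3-3zeta	R18-E89	R	18	E	89	N-terminal dimer interface bridge of human 14-3-3zeta
hzeta_homo	h14-3-3zeta	h14-3-3zeta	E5-K74	E	5	K	74	N-terminal dimer interface bridge of human 14-3-3zeta
hzeta_homo	h14-3-3zeta	h14-3-3zeta	D21-K85	D	21	K	85	N-terminal dimer interface bridge of human 14-3-3zeta
leoii_homo	LeoII	LeoII	R21-E92	R	21	E	92	LeoII residues homologous to the human zeta bridges
leoii_homo	LeoII	LeoII	E8-R77	E	8	R	77	LeoII residues homologous to the human zeta bridges
leoii_homo	LeoII	LeoII	D24-R88	D	24	R	88	LeoII residues homologous to the human zeta bridges
d14e_homo	D14-3-3e	D14-3-3e	R19-E92	R	19	E	92	only formable bridge of the epsilon homodimer
d14e_homo	D14-3-3e	D14-3-3e	N6-E77	N	6	E	77	zeta E5-K74 positions substituted in epsilon
d14e_homo	D14-3-3e	D14-3-3e	E22-Q88	E	22	Q	88	zeta D21-K85 positions substituted in epsilon
g14_homo	g14-3-3	g14-3-3	R22-E97	R	22	E	97	Giardia homodimer bridge
g14_homo	g14-3-3	g14-3-3	D9-K82	D	9	K	82	Giardia homodimer bridge
g14_homo	g14-3-3	g14-3-3	E25-K93	E	25	K	93	Giardia homodimer bridge
g14_leoii	g14-3-3	LeoII	gD9-dR77	D	9	R	77	Giardia/LeoII heterodimer pairing
g14_leoii	g14-3-3	LeoII	gE25-dR88	E	25	R	88	Giardia/LeoII heterodimer pairing
g14_leoii	g14-3-3	LeoII	gR22-dE92	R	22	E	92	Giardia/LeoII heterodimer pairing
g14_d14e	g14-3-3	D14-3-3e	gR22-dE92	R	22	E	92	lone formable bridge of the Giardia/epsilon heterodimer
g14_d14e	g14-3-3	D14-3-3e	gD9-dE77	D	9	E	77	like-charge pairing, predicted repulsion
g14_d14e	g14-3-3	D14-3-3e	gE25-dQ88	E	25	Q	88	charged/polar pairing, no bridge
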