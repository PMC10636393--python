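label	protocol	full_name	location	network	n_patients	outside_dlpfc
L46	cTBS	Left area 46	Brodmann area 46	Salience	3	0
L46	iTBS	Right area 46	Brodmann area 46	Salience	1	0
L8Av	cTBS	Left area 8Av	Dorsolateral prefrontal cortex	CEN	17	0
L8Av	iTBS	Left area 8Av	Dorsolateral prefrontal cortex	CEN	2	0
LPFm	cTBS	Left area PFm complex	Inferior parietal cortex	CEN	6	1
LPGs	cTBS	Left area PGs	Inferior parietal cortex	CEN	13	1
LPi	cTBS	Para-insular area	Para-insular cortex	Salience	1	1
Ls6-8	cTBS	Left superior 6-8 transition area	Dorsolateral prefrontal cortex	CEN	5	0
LTe1m	cTBS	Left area TE1 middle	Lateral temporal cortex	CEN	7	1
LTe1m	iTBS	Left area TE1 middle	Lateral temporal cortex	CEN	1	1
R43	cTBS	Right area 43	Brodmann area 43	CEN	2	1
R46	iTBS	Right area 46	Brodmann area 46	Salience	1	0
R5mv	cTBS	Right area 5 m ventral	Paracentral lobule	Salience	1	1
R8Av	cTBS	Right area 8Av	Dorsolateral prefrontal cortex	CEN	2	0
RIFJp	iTBS	Right area IFJp	Dorsolateral prefrontal cortex	CEN	1	0
Rp47r	iTBS	Right area posterior 47r	Dorsolateral prefrontal cortex	CEN	1	0
RPFm	cTBS	Right area PFm complex	Inferior parietal cortex	CEN	1	1
Rs6-8	cTBS	Right superior 6-8 transition area	Dorsolateral prefrontal cortex	CEN	4	0
RTe1m	cTBS	Right area TE1 middle	Lateral temporal cortex	CEN	7	1
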