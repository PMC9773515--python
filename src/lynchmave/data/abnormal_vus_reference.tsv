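gene	hgvs_c	hgvs_p	consequence	classification	lof_score	spliceai_deltamax	gnomad_af	evidence_codes
MSH2	c.2083G>A	p.Val695Met	missense	VUS	4.511			PM2_P,PP4
MSH2	c.929T>G	p.Leu310Arg	missense	VUS	3.774			PM2_P,PP4,PP3,PP1
MSH2	c.1568T>C	p.Phe523Ser	missense	VUS	3.547			PM2_P,PP4,PM1
MSH2	c.443T>A	p.Val148Glu	missense	VUS	3.239			PM2_P,PP4
MSH2	c.2011A>T	p.Asn671Tyr	missense	VUS	3.114			PM2_P,PS4_M,PP3,PM1_P
MSH2	c.1808A>T	p.Asp603Val	missense	VUS	2.999			PM2_P,PP4,PP3
MSH2	c.1067T>A	p.Ile356Lys	missense	VUS	2.518			PM2_P,PP4,PP3
MSH2	c.2030C>G	p.Thr677Arg	missense	VUS	2.469			PM2_P,PP4,PP3,PM1
MSH2	c.2276G>T	p.Gly759Val	missense	VUS	2.215			PM2_P,PP3
MSH2	c.2281G>C	p.Gly761Arg	missense	VUS	2.193			PM2_P,PM1_P
MSH2	c.2272G>T	p.Asp758Tyr	missense	VUS	1.955			PM2_P
MSH2	c.2099C>A	p.Ala700Glu	missense	VUS	1.917			PM2_P,PP4
MSH2	c.2282G>T	p.Gly761Val	missense	VUS	1.785			PM2_P
MSH2	c.1241T>C	p.Leu414Pro	missense	VUS	1.766			PM2_P,PP4,PM1
MSH2	c.2768T>A	p.Val923Glu	missense	VUS	1.669			PM2_P,BS2_P
MSH2	c.1654A>C	p.Thr552Pro	missense	VUS	1.61			PM2_P,PS4_M
MSH2	c.1601G>C	p.Arg534Pro	missense	VUS	1.383			PM2_P
MSH2	c.1703C>T	p.Thr568Ile	missense	VUS	0.932			PM2_P,BP4
MSH2	c.1862G>C	p.Arg621Pro	missense	VUS	0.745			PM2_P,PP4
MSH2	c.2272G>C	p.Asp758His	missense	VUS	0.701			PM2_P
MSH2	c.386C>G	p.Ser129Cys	missense	VUS	0.574		2.35e-05	PP4,BS2_P
MSH2	c.925G>C	p.Ala309Pro	missense	VUS	0.528			PM2_P,PP3
MSH2	c.2132G>T	p.Arg711Leu	missense	VUS	0.491			PM2_P,BS2_P,PP3
MSH2	c.1571G>T	p.Arg524Leu	missense	VUS	0.449			PM2_P
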