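gene	refseq	chrom	position	ref	alt	coding_change	location	rs_id	patient_id	inheritance	phenotype	familial	zygosity	KG_ALL	KG_EUR	EVS	ExAC	MGP	sift	polyphen
BBX	NM_020235	3	107466840	C	T	c.779C>T:p.Ala260Val	exon	rs150121801	3733	father	S-HSCR	false	het	0.0012	0.002	0.0012	0.0026	N	T	B
BBX	NM_020235	3	107435532	C	T	c.241C>T:p.Arg81Trp	exon	rs142400819	4086	mother	S-HSCR	true	het	0.0030	0.007	0.0030	0.0028	0.006	D	D
SULF1	NM_015170	8	70541785	AAC	-	c.2155_2157delAAC:p.Asn720del	exon	rs150178205	10943	mother	L-HSCR	false	het	0.0038	N	0.0045	0.0009	0.002	Neutral	N
RAB10	NM_016131	2	26257138	C	T	c.-340C>T	utr5	rs112783454	4949	father	S-HSCR	false	het	0.0052	0.012	N	N	0.008	N	N
RAB10	NM_016131	2	26257109	GA	-	c.-369_-368delGA	utr5	rs74587659	4462	father	S-HSCR	false	het	N	N	N	N	N	N	N
PPP2R2B	NM_181674	5	145979904	C	T	c.1108G>A:p.Val370Ile	exon	rs369931023	3485	father	S-HSCR	false	het	0.0002	N	0.00008	0.00006	N	T	B
PPP2R2B	NM_181674	5	146017897	T	C	c.905A>G:p.Asn302Ser	exon	rs150981315	3708	father	S-HSCR	false	het	N	N	0.0003	0.0004	N	D	B
PPP2R2B	NM_181674	5	145969279	G	C	c.*231C>G	utr3	rs141447016	3364	mother	L-HSCR	false	het	0.0038	0.007	N	N	N	N	N
CDK5RAP2	NM_018249	9	123334309	G	T	c.70C>A:p.Pro24Thr	exon	N	3606	father	S-HSCR	false	het	N	N	N	N	N	T	B
CDK5RAP2	NM_018249	9	123216045	T	C	c.2482A>G:p.Lys828Glu	exon	rs549081765	8079	mother	S-HSCR	false	het	0.0004	N	N	0.0002	N	T	B
CDK5RAP2	NM_018249	9	123253661	T	C	c.1406A>G:p.Asn469Ser	exon	rs754779136	8079	father	S-HSCR	false	het	N	N	N	0.000008	N	T	B
CDK5RAP2	NM_018249	9	123287277	G	A	c.1079C>T:p.Thr360Ile	exon	rs145165171	10943	father	L-HSCR	false	het	0.001	0.004	0.001	0.0009	0.002	T	B
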