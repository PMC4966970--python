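kind	position	end	ref	alt	region	effect	codon	minority	context
substitution	5697	5697	A	G	ORF10	synonymous	.	0	.
substitution	11428	11428	G	A	ORF14	synonymous	.	1	.
substitution	11902	11902	G	T	ORF14	synonymous	.	0	.
substitution	12346	12346	G	A	ORF14	nonsynonymous	.	1	.
insertion	12508	12508	.	A	ORF14	frameshift	7	1	A:8>9
deletion	12640	12750	.	.	intergenic	intergenic	.	0	.
deletion	12790	12792	.	.	intergenic	intergenic	.	0	.
substitution	13000	13000	T	C	ORF15	synonymous	.	1	.
substitution	13487	13487	G	A	ORF15	synonymous	.	0	.
substitution	13624	13624	A	G	ORF15	synonymous	.	0	.
deletion	18562	18635	.	.	intergenic	intergenic	.	0	.
deletion	18777	18777	.	.	intergenic	intergenic	.	0	T:4>3
substitution	18910	18910	C	A	ORF21	nonsynonymous	.	0	.
substitution	19166	19166	C	A	ORF21	nonsynonymous	.	0	.
substitution	19216	19216	G	A	ORF21	nonsynonymous	.	0	.
substitution	19248	19248	A	G	ORF21	nonsynonymous	.	0	.
substitution	19307	19307	A	G	ORF21	synonymous	.	1	.
insertion	19336	19336	.	GGT	ORF21	in-frame	.	1	.
substitution	19367	19367	A	G	ORF21	synonymous	.	1	.
insertion	19495	19495	.	CTTCAGACG	ORF21	in-frame	.	1	.
deletion	19809	19809	.	.	intergenic	intergenic	.	0	.
substitution	19960	19960	T	G	intergenic	intergenic	.	1	.
substitution	19963	19963	T	G	intergenic	intergenic	.	0	.
deletion	20106	20114	.	.	ORF22	in-frame	.	1	.
substitution	21721	21721	A	T	ORF24	nonsynonymous	.	0	.
substitution	22038	22038	T	C	intergenic	intergenic	.	0	.
deletion	22215	22224	.	.	intergenic	intergenic	.	1	.
deletion	22250	22250	.	.	intergenic	intergenic	.	0	.
deletion	22412	22412	.	.	intergenic	intergenic	.	0	.
substitution	22788	22788	A	G	intergenic	intergenic	.	1	.
deletion	23361	23363	.	.	ORF25	in-frame	.	0	.
substitution	23412	23412	G	A	ORF25	nonsynonymous	.	0	.
insertion	23523	23523	.	AACTTTCCAGCT	ORF25	in-frame	.	1	.
insertion	23594	23594	.	CGTCGACGAGCC	ORF25	in-frame	.	0	.
substitution	23649	23649	A	G	ORF25	nonsynonymous	.	0	.
deletion	23669	23692	.	.	ORF25	in-frame	.	0	.
substitution	23708	23708	A	G	ORF25	synonymous	.	0	.
substitution	23738	23738	T	A	ORF25	synonymous	.	0	.
insertion	23786	23786	.	AAAAAG	ORF25	in-frame	.	0	.
deletion	24679	24679	.	.	intergenic	intergenic	.	0	A:9>8
insertion	24699	24699	.	T	intergenic	intergenic	.	0	T:9>10
substitution	25274	25274	C	T	ORF26	nonsynonymous	.	0	.
substitution	27052	27052	C	T	ORF27	synonymous	.	1	.
substitution	30502	30502	C	T	ORF30	synonymous	.	0	.
substitution	31352	31352	C	T	ORF31	synonymous	.	1	.
substitution	31427	31427	G	A	ORF32	nonsynonymous	.	1	.
substitution	31440	31440	G	A	ORF32	nonsynonymous	.	1	.
substitution	32000	32000	G	T	ORF32	nonsynonymous	.	0	.
substitution	32183	32183	G	A	ORF32	synonymous	.	0	.
substitution	32591	32591	C	T	ORF32	synonymous	.	0	.
deletion	33295	33357	.	.	ORF32	in-frame	.	0	.
substitution	33677	33677	C	T	ORF33	synonymous	.	1	.
substitution	33929	33929	G	A	intergenic	intergenic	.	0	.
substitution	33939	33939	A	G	intergenic	intergenic	.	1	.
substitution	34556	34556	A	G	ORF35	nonsynonymous	.	1	.
substitution	34578	34578	T	C	ORF35	nonsynonymous	.	1	.
substitution	34579	34579	A	C	ORF35	nonsynonymous	.	1	.
substitution	34689	34689	G	T	ORF35	synonymous	.	1	.
substitution	64930	64930	C	T	ORF75	synonymous	.	1	.
substitution	65260	65260	G	C	ORF75	synonymous	.	1	.
substitution	68357	68357	C	T	ORF77	synonymous	.	1	.
substitution	72799	72799	A	G	ORF81	nonsynonymous	.	1	.
substitution	73652	73652	A	G	ORF82	synonymous	.	1	.
substitution	73660	73660	T	G	ORF82	nonsynonymous	.	1	.
deletion	76289	76310	.	.	ORF85	no-aa-impact	.	0	.
substitution	77453	77453	A	C	ORF86	synonymous	.	0	.
substitution	79226	79226	C	T	intergenic	intergenic	.	0	.
substitution	79375	79375	G	A	intergenic	intergenic	.	0	.
substitution	80342	80342	A	G	ORF90	nonsynonymous	.	0	.
substitution	82426	82426	T	A	ORF93	synonymous	.	1	.
substitution	82575	82575	G	A	ORF93	nonsynonymous	.	1	.
substitution	83369	83369	G	A	ORF95	nonsynonymous	.	1	.
substitution	86263	86263	A	G	ORF96	synonymous	.	1	.
substitution	86772	86772	A	G	ORF97	synonymous	.	1	.
substitution	87134	87134	A	G	ORF97	nonsynonymous	.	1	.
substitution	88503	88503	C	A	ORF97	nonsynonymous	.	0	.
substitution	88667	88667	C	A	ORF97	nonsynonymous	.	1	.
substitution	88858	88858	T	C	intergenic	intergenic	.	0	.
substitution	88861	88861	T	C	intergenic	intergenic	.	0	.
substitution	89257	89257	G	A	ORF98	synonymous	.	1	.
substitution	90715	90715	C	T	ORF100	synonymous	.	1	.
substitution	91296	91296	T	C	ORF101	synonymous	.	1	.
substitution	92715	92715	G	A	ORF102	synonymous	.	1	.
substitution	92800	92800	G	A	ORF102	nonsynonymous	.	1	.
substitution	92804	92804	C	A	ORF102	nonsynonymous	.	1	.
substitution	93097	93097	C	A	ORF102	nonsynonymous	.	0	.
insertion	93363	93363	.	T	intergenic	intergenic	.	0	T:6>7
deletion	96280	96280	.	.	hr6	intergenic	.	0	T:5>4
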