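gene	element_type	name	start	end	frame_or_aa
FGFR1	gene	FGFR1	38270583	38326352	-
FGFR1	exon	1	38326052	38326352	-
FGFR1	exon	2	38323232	38323552	-
FGFR1	exon	3	38320082	38320232	-
FGFR1	exon	4	38317132	38317282	-
FGFR1	exon	5	38313812	38313932	-
FGFR1	exon	6	38311002	38311212	-
FGFR1	exon	7	38307752	38307902	-
FGFR1	exon	8	38304672	38304852	-
FGFR1	exon	9	38301192	38301372	-
FGFR1	exon	10	38298342	38298492	-
FGFR1	exon	11	38294804	38294942	-
FGFR1	exon	12	38291666	38291804	-
FGFR1	exon	13	38288628	38288766	-
FGFR1	exon	14	38285390	38285528	-
FGFR1	exon	15	38281752	38281890	-
FGFR1	exon	16	38278814	38278952	-
FGFR1	exon	17	38275482	38275614	-
FGFR1	exon	18	38270583	38271882	-
FGFR1	cds	cds	38323351	38271783	-
FGFR1	tss	tss	38326351	38326352	-
FGFR1	domain	IG-I	25	119	aa
FGFR1	domain	acid box	126	138	aa
FGFR1	domain	IG-II	158	246	aa
FGFR1	domain	IG-III	255	357	aa
FGFR1	domain	TM	377	397	aa
FGFR1	domain	kinase	478	767	aa
NSD3	gene	NSD3	38132000	38237764	+
NSD3	exon	1	38132000	38132250	+
NSD3	exon	2	38136450	38136700	+
NSD3	exon	3	38141100	38141290	+
NSD3	exon	4	38145590	38145780	+
NSD3	exon	5	38150280	38150470	+
NSD3	exon	6	38155070	38155260	+
NSD3	exon	7	38159360	38159550	+
NSD3	exon	8	38163950	38164140	+
NSD3	exon	9	38168340	38168530	+
NSD3	exon	10	38173030	38173220	+
NSD3	exon	11	38177520	38177710	+
NSD3	exon	12	38182310	38182500	+
NSD3	exon	13	38186900	38187090	+
NSD3	exon	14	38191290	38191480	+
NSD3	exon	15	38195980	38196170	+
NSD3	exon	16	38200270	38200460	+
NSD3	exon	17	38204760	38204950	+
NSD3	exon	18	38209550	38209740	+
NSD3	exon	19	38213940	38214130	+
NSD3	exon	20	38218530	38218720	+
NSD3	exon	21	38223220	38223410	+
NSD3	exon	22	38227710	38227900	+
NSD3	exon	23	38232000	38232190	+
NSD3	exon	24	38236790	38237764	+
NSD3	cds	cds	38136550	38236963	+
NSD3	tss	tss	38132000	38132001	+
NSD3	domain	PWWP	270	330	aa
NSD3	domain	SET	1070	1310	aa
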