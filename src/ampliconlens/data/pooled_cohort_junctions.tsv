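sample	name	chrom_a	pos_a	side_a	chrom_b	pos_b	side_b	support	provenance
TUM004	tt_intragenic	chr8	38324802	left	chr8	38340000	left	192	reported_support
TUM006	tt_intragenic	chr8	38318682	left	chr8	38360000	left	115	reported_support
TUM009	tt_upstream	chr8	38592000	left	chr8	38690000	left	35	representative
TUM009	nsd3_fusion	chr8	38196075	left	chr8	41510000	left	28	representative
TUM010	hh_distal	chr8	37500000	right	chr8	37600000	right	12	representative
H1581	tt_upstream	chr8	38595657	left	chr8	38650000	left	40	reported_coordinate
H1581	nsd3_fusion	chr8	38196075	left	chr8	41510000	left	25	reported_exon
DMS114	tt_upstream	chr8	38382689	left	chr8	38500000	left	33	reported_coordinate
PDX003	tt_upstream	chr8	38371080	left	chr8	38430000	left	30	reported_coordinate
PDX003	nsd3_del_16_24	chr8	38198220	left	chr8	38242764	right	22	reported_exons
PDX006	nsd3_del_9_24	chr8	38166240	left	chr8	38243764	right	19	reported_exons
PDX006	tt_distal	chr8	39200000	left	chr8	39300000	left	9	representative
PDX008	tt_upstream	chr8	38481135	left	chr8	38550000	left	27	reported_coordinate
PDX008	nsd3_del_9_24	chr8	38166240	left	chr8	38244764	right	21	reported_exons
TUM001	del_distal	chr8	30000000	left	chr8	30500000	right	14	representative
TUM002	tt_upstream	chr8	38450000	left	chr8	38520000	left	18	representative
TUM003	hh_upstream	chr8	38400000	right	chr8	38410000	right	11	representative
TUM005	tt_distal	chr8	38900000	left	chr8	38950000	left	16	representative
TUM008	dup_distal	chr8	37800000	right	chr8	37900000	left	10	representative
CL001	tt_upstream	chr8	38600123	left	chr8	38640000	left	23	representative
PDX001	hh_kinase_del	chr8	38050000	right	chr8	38312512	right	26	reported_exons
PDX002	tt_distal	chr8	38800000	left	chr8	38850000	left	13	representative
PDX004	tt_upstream	chr8	38700500	left	chr8	38720000	left	17	representative
PDX005	del_distal	chr8	39500000	left	chr8	39600000	right	15	representative
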