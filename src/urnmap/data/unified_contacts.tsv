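# Unified contact maps for HLA-II DR and DQ groups: similar-contact (SC)
# triples (peptide URN position, chain role, chain position), the secondary-
# structure unit holding the chain position, and the percentage of
# non-prototype structures in the group exhibiting the SC.
group	peptide_pos	chain_role	chain_pos	ss_unit	pct_structures
dr	3	alpha	51	loop h1-h2	100
dr	3	alpha	52	loop h1-h2	98
dr	3	alpha	53	loop h1-h2	100
dr	4	alpha	53	loop h1-h2	100
dr	4	alpha	54	loop h1-h2	87
dr	5	alpha	7	strand 1	68
dr	5	alpha	24	strand 2	100
dr	5	alpha	31	strand 3	98
dr	5	alpha	32	strand 3	100
dr	5	alpha	43	strand 4	100
dr	5	alpha	52	loop h1-h2	100
dr	5	alpha	53	loop h1-h2	100
dr	5	alpha	54	loop h1-h2	100
dr	5	alpha	55	loop h1-h2	64
dr	6	alpha	24	strand 2	98
dr	6	alpha	54	loop h1-h2	76
dr	7	alpha	9	strand 1	100
dr	7	alpha	22	strand 2	100
dr	7	alpha	24	strand 2	89
dr	7	alpha	54	loop h1-h2	100
dr	7	alpha	58	helix 2	98
dr	7	alpha	59	helix 2	41
dr	7	alpha	61	helix 2	37
dr	7	alpha	62	helix 2	100
dr	8	alpha	9	strand 1	100
dr	8	alpha	62	helix 2	98
dr	9	alpha	62	helix 2	100
dr	9	alpha	65	helix 2	26
dr	10	alpha	11	strand 1	71
dr	10	alpha	62	helix 2	98
dr	10	alpha	65	helix 2	100
dr	10	alpha	66	helix 2	98
dr	10	alpha	69	helix 2	81
dr	11	alpha	65	helix 2	100
dr	11	alpha	69	helix 2	98
dr	12	alpha	65	helix 2	100
dr	12	alpha	68	helix 2	87
dr	12	alpha	69	helix 2	100
dr	12	alpha	72	helix 2	57
dr	13	alpha	69	helix 2	100
dr	13	alpha	72	helix 2	100
dr	13	alpha	73	helix 2	93
dr	13	alpha	76	helix 2	91
dr	14	alpha	72	helix 2	100
dr	14	alpha	76	helix 2	89
dr	3	beta	81	helix 4	61
dr	3	beta	85	helix 4	100
dr	4	beta	81	helix 4	100
dr	4	beta	85	helix 4	100
dr	5	beta	82	helix 4	100
dr	5	beta	85	helix 4	100
dr	5	beta	86	helix 4	98
dr	5	beta	89	helix 4	79
dr	6	beta	77	helix 3	98
dr	6	beta	78	helix 3	100
dr	6	beta	81	helix 4	100
dr	6	beta	82	helix 4	100
dr	7	beta	78	helix 3	98
dr	8	beta	13	strand 1	100
dr	8	beta	26	strand 2	89
dr	8	beta	71	helix 3	91
dr	8	beta	74	helix 3	84
dr	8	beta	78	helix 3	100
dr	9	beta	13	strand 1	80
dr	9	beta	71	helix 3	91
dr	10	beta	11	strand 1	94
dr	10	beta	13	strand 1	68
dr	10	beta	28	strand 2	38
dr	10	beta	71	helix 3	47
dr	11	beta	28	strand 2	66
dr	11	beta	47	strand 4	85
dr	11	beta	61	helix 2	100
dr	11	beta	67	helix 3	100
dr	11	beta	70	helix 3	23
dr	11	beta	71	helix 3	94
dr	12	beta	60	helix 2	87
dr	12	beta	61	helix 2	100
dr	13	beta	9	strand 1	65
dr	13	beta	57	helix 2	100
dr	13	beta	60	helix 2	89
dr	13	beta	61	helix 2	100
dr	14	beta	57	helix 2	84
dr	14	beta	60	helix 2	96
dq	4	alpha	52	loop h1-h2	53
dq	4	alpha	54	loop h1-h2	72
dq	5	alpha	9	strand 1	56
dq	5	alpha	24	strand 2	100
dq	5	alpha	31	strand 3	59
dq	5	alpha	32	strand 3	94
dq	5	alpha	43	strand 4	84
dq	5	alpha	48	helix 1	6
dq	5	alpha	51	loop h1-h2	69
dq	5	alpha	52	loop h1-h2	97
dq	5	alpha	54	loop h1-h2	100
dq	6	alpha	9	strand 1	38
dq	6	alpha	24	strand 2	100
dq	6	alpha	54	loop h1-h2	47
dq	7	alpha	9	strand 1	72
dq	7	alpha	22	strand 2	100
dq	7	alpha	24	strand 2	97
dq	7	alpha	54	loop h1-h2	100
dq	7	alpha	58	helix 2	97
dq	7	alpha	62	helix 2	44
dq	8	alpha	9	strand 1	91
dq	8	alpha	11	strand 1	84
dq	8	alpha	22	strand 2	81
dq	8	alpha	62	helix 2	100
dq	9	alpha	61	helix 2	34
dq	9	alpha	62	helix 2	100
dq	10	alpha	11	strand 1	28
dq	10	alpha	62	helix 2	100
dq	10	alpha	65	helix 2	100
dq	10	alpha	66	helix 2	100
dq	10	alpha	69	helix 2	97
dq	11	alpha	65	helix 2	91
dq	11	alpha	69	helix 2	100
dq	12	alpha	65	helix 2	100
dq	12	alpha	68	helix 2	100
dq	12	alpha	69	helix 2	97
dq	13	alpha	68	helix 2	100
dq	13	alpha	69	helix 2	100
dq	13	alpha	72	helix 2	100
dq	13	alpha	73	helix 2	100
dq	13	alpha	76	helix 2	78
dq	14	alpha	68	helix 2	46
dq	14	alpha	72	helix 2	79
dq	4	beta	81	helix 5	94
dq	4	beta	85	helix 5	88
dq	5	beta	82	helix 5	100
dq	5	beta	85	helix 5	100
dq	5	beta	86	helix 5	31
dq	6	beta	76	helix 4	0
dq	6	beta	77	helix 4	100
dq	6	beta	78	helix 4	100
dq	6	beta	81	helix 5	94
dq	6	beta	82	helix 5	100
dq	7	beta	77	helix 4	22
dq	7	beta	78	helix 4	100
dq	8	beta	11	strand 1	100
dq	8	beta	13	strand 1	100
dq	8	beta	26	strand 2	91
dq	8	beta	28	strand 2	97
dq	8	beta	71	helix 3	56
dq	8	beta	74	helix 4	100
dq	8	beta	77	helix 4	19
dq	8	beta	78	helix 4	100
dq	9	beta	11	strand 1	100
dq	9	beta	70	helix 3	50
dq	9	beta	71	helix 3	75
dq	9	beta	77	helix 4	22
dq	10	beta	9	strand 1	75
dq	10	beta	11	strand 1	100
dq	11	beta	11	strand 1	19
dq	11	beta	47	strand 4	100
dq	11	beta	61	helix 2	100
dq	11	beta	67	helix 3	100
dq	11	beta	71	helix 3	69
dq	12	beta	60	helix 2	94
dq	12	beta	61	helix 2	100
dq	13	beta	9	strand 1	53
dq	13	beta	37	strand 3	88
dq	13	beta	38	strand 3	25
dq	13	beta	53	helix 1	28
dq	13	beta	57	helix 2	100
dq	13	beta	60	helix 2	78
dq	13	beta	61	helix 2	100
dq	14	beta	57	helix 2	75
dq	14	beta	60	helix 2	96
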