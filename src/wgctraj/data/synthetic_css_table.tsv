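# SYNTHETIC identity placeholder calibration table - NOT a published ADOS calibration.
# severity = clip(social+communication total, 1, 10) for every module and age band.
ados_module	age_min	age_max	total_min	total_max	severity
1	2	99	0	0	1
1	2	99	1	1	1
1	2	99	2	2	2
1	2	99	3	3	3
1	2	99	4	4	4
1	2	99	5	5	5
1	2	99	6	6	6
1	2	99	7	7	7
1	2	99	8	8	8
1	2	99	9	9	9
1	2	99	10	10	10
1	2	99	11	11	10
1	2	99	12	12	10
1	2	99	13	13	10
1	2	99	14	14	10
1	2	99	15	15	10
1	2	99	16	16	10
1	2	99	17	17	10
1	2	99	18	18	10
1	2	99	19	19	10
1	2	99	20	20	10
1	2	99	21	21	10
1	2	99	22	22	10
2	2	99	0	0	1
2	2	99	1	1	1
2	2	99	2	2	2
2	2	99	3	3	3
2	2	99	4	4	4
2	2	99	5	5	5
2	2	99	6	6	6
2	2	99	7	7	7
2	2	99	8	8	8
2	2	99	9	9	9
2	2	99	10	10	10
2	2	99	11	11	10
2	2	99	12	12	10
2	2	99	13	13	10
2	2	99	14	14	10
2	2	99	15	15	10
2	2	99	16	16	10
2	2	99	17	17	10
2	2	99	18	18	10
2	2	99	19	19	10
2	2	99	20	20	10
2	2	99	21	21	10
2	2	99	22	22	10
3	2	99	0	0	1
3	2	99	1	1	1
3	2	99	2	2	2
3	2	99	3	3	3
3	2	99	4	4	4
3	2	99	5	5	5
3	2	99	6	6	6
3	2	99	7	7	7
3	2	99	8	8	8
3	2	99	9	9	9
3	2	99	10	10	10
3	2	99	11	11	10
3	2	99	12	12	10
3	2	99	13	13	10
3	2	99	14	14	10
3	2	99	15	15	10
3	2	99	16	16	10
3	2	99	17	17	10
3	2	99	18	18	10
3	2	99	19	19	10
3	2	99	20	20	10
3	2	99	21	21	10
3	2	99	22	22	10
4	2	99	0	0	1
4	2	99	1	1	1
4	2	99	2	2	2
4	2	99	3	3	3
4	2	99	4	4	4
4	2	99	5	5	5
4	2	99	6	6	6
4	2	99	7	7	7
4	2	99	8	8	8
4	2	99	9	9	9
4	2	99	10	10	10
4	2	99	11	11	10
4	2	99	12	12	10
4	2	99	13	13	10
4	2	99	14	14	10
4	2	99	15	15	10
4	2	99	16	16	10
4	2	99	17	17	10
4	2	99	18	18	10
4	2	99	19	19	10
4	2	99	20	20	10
4	2	99	21	21	10
4	2	99	22	22	10
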