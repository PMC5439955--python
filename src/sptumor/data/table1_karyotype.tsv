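tumor_id	chrom	copy_number	major	minor	arm_copy	arm_zygosity
SpT1	chr1	4	2	2
SpT1	chr2	3	2	1
SpT1	chr3	3	2	1
SpT1	chr4	3	2	1
SpT1	chr5	4	3	1	5	3:2
SpT1	chr6	5	3	2
SpT1	chr7	2	1	1
SpT1	chr8	3	2	1
SpT1	chr9	5	3	2
SpT1	chr10	4	2	2
SpT1	chr11	3	2	1
SpT1	chr12	3	2	1
SpT1	chr13	3	3	0
SpT1	chr14	4	3	1
SpT1	chr15	3	2	1
SpT1	chr16	3	2	1
SpT1	chr17	4	3	1
SpT1	chr18	3	2	1
SpT1	chr19	4	3	1
SpT1	chr20	5	3	2
SpT1	chr21	3	2	1
SpT1	chr22	2	1	1
SpT1	chrX	2	2	0
SpT1	chrY	2	2	0
SpT3	chr1	4	2	2
SpT3	chr2	4	2	2
SpT3	chr3	4	2	2
SpT3	chr4	4	2	2
SpT3	chr5	4	2	2
SpT3	chr6	6	5	1
SpT3	chr7	5	3	2
SpT3	chr8	3	2	1
SpT3	chr9	6	4	2
SpT3	chr10	5	3	2
SpT3	chr11	4	2	2
SpT3	chr12	4	2	2
SpT3	chr13	3	2	1
SpT3	chr14	3	2	1
SpT3	chr15	3	2	1
SpT3	chr16	4	2	2
SpT3	chr17	4	2	2
SpT3	chr18	4	2	2
SpT3	chr19	5	3	2
SpT3	chr20	8	6	2
SpT3	chr21	8	6	2
SpT3	chr22	4	2	2
SpT3	chrX	2	2	0
SpT3	chrY	2	2	0
SpT4	chr1	3	2	1
SpT4	chr2	2	1	1
SpT4	chr3	2	1	1
SpT4	chr4	2	1	1
SpT4	chr5	2	1	1
SpT4	chr6	2	1	1
SpT4	chr7	2	1	1
SpT4	chr8	2	1	1
SpT4	chr9	3	2	1	4-5	3:1-4:1
SpT4	chr10	2	1	1
SpT4	chr11	2	1	1
SpT4	chr12	2	1	1
SpT4	chr13	2	1	1
SpT4	chr14	3	2	1
SpT4	chr15	2	1	1
SpT4	chr16	2	1	1
SpT4	chr17	2	1	1
SpT4	chr18	3	2	1
SpT4	chr19	2	1	1
SpT4	chr20	4	2	2
SpT4	chr21	2	1	1
SpT4	chr22	2	1	1
SpT4	chrX	1	1	0
SpT4	chrY	1	1	0
SpT6	chr1	3	2	1
SpT6	chr2	3	2	1
SpT6	chr3	3	2	1
SpT6	chr4	2	1	1
SpT6	chr5	3	2	1
SpT6	chr6	4	3	1
SpT6	chr7	2	1	1
SpT6	chr8	3	2	1
SpT6	chr9	4	3	1	5	4:1
SpT6	chr10	3	2	1
SpT6	chr11	2	1	1
SpT6	chr12	3	2	1
SpT6	chr13	3	2	1
SpT6	chr14	3	2	1
SpT6	chr15	2	1	1
SpT6	chr16	3	2	1
SpT6	chr17	3	2	1
SpT6	chr18	3	2	1
SpT6	chr19	3	2	1
SpT6	chr20	4	2	2
SpT6	chr21	3	2	1
SpT6	chr22	2	1	1
SpT6	chrX	2	2	0
SpT6	chrY	1	1	0
SpT8	chr1	3	2	1
SpT8	chr2	3	2	1
SpT8	chr3	4	3	1
SpT8	chr4	3	2	1
SpT8	chr5	3	2	1
SpT8	chr6	4	3	1
SpT8	chr7	2	1	1
SpT8	chr8	3	3	0
SpT8	chr9	5	4	1
SpT8	chr10	5	3	2
SpT8	chr11	3	2	1
SpT8	chr12	3	2	1
SpT8	chr13	2	1	1
SpT8	chr14	3	2	1
SpT8	chr15	2	2	0
SpT8	chr16	3	2	1
SpT8	chr17	3	2	1
SpT8	chr18	4	2	2
SpT8	chr19	3	2	1
SpT8	chr20	5	3	2
SpT8	chr21	4	3	1
SpT8	chr22	2	1	1
SpT8	chrX	2	2	0
SpT8	chrY	2	2	0
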