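miRNA	Tot	mRNP	60S	80S	Poly	G
dme-miR-286-3p	2.6	3.1	2.2	2.1	1.6	G1
dme-miR-283-5p	3.6	1.5	1.3	1.3	1.3	G1
dme-miR-7-5p	2.0	4.5	2.0	2.1	1.3	G1
dme-miR-957-3p	2.6	1.3	1.2	1.2	0.8	G1
dme-miR-263a-5p	1.6	1.1	2.3	1.3	0.4	G1
dme-miR-315-5p	3.9	2.6	1.3	1.3	0.2	G1
dme-miR-314-3p	5.6	2.1	1.3	1.0	0.0	G1
dme-bantam-5p	2.6	1.7	1.5	1.2	-0.8	G1
dme-miR-958-3p	7.0	3.6	1.1	0.8	1.8	G1
dme-miR-956-3p	3.3	1.2	1.0	0.6	0.7	G1
dme-miR-998-3p	1.3	1.2	1.5	0.5	0.4	G1
dme-miR-2c-5p	1.4	1.2	1.6	0.2	0.2	G1
dme-miR-304-5p	6.0	1.5	0.9	0.5	0.1	G1
dme-miR-8-3p	1.1	1.8	0.8	0.5	1.3	G1
dme-miR-983-5p	2.0	1.2	0.7	0.3	0.0	G1
dme-bantam-3p	4.6	4.3	0.4	0.3	-0.5	G1
dme-miR-2b-3p	1.6	1.2	0.4	0.8	-1.1	G1
dme-miR-276a-3p	3.3	0.9	1.4	1.0	0.8	G1
dme-miR-5-3p	2.7	0.8	1.7	1.0	2.2	G1
dme-miR-263b-5p	1.5	0.7	1.9	1.2	1.5	G1
dme-miR-137-3p	1.3	-0.6	1.6	1.3	1.4	G1
dme-miR-1002-5p	3.1	-0.2	1.2	1.9	1.4	G1
dme-miR-10-5p	1.9	0.2	1.2	0.7	2.2	G1
dme-miR-252-5p	1.5	0.8	1.7	0.7	0.5	G1
dme-miR-316-5p	3.4	0.0	1.3	0.9	-0.1	G1
dme-miR-1006-3p	2.5	0.5	1.1	0.5	0.0	G1
dme-miR-968-5p	4.2	0.6	1.1	0.3	0.0	G1
dme-miR-1000-5p	1.9	0.1	1.1	0.6	0.7	G1
dme-miR-987-5p	2.1	0.7	0.2	0.1	1.1	G1
dme-miR-31a-5p	1.3	0.9	0.5	0.1	0.8	G1
dme-miR-13b-3p	1.1	0.1	0.9	0.7	0.5	G1
dme-miR-927-3p	1.8	0.6	0.6	0.6	0.5	G1
dme-miR-996-3p	1.0	-0.2	-0.2	0.2	0.1	G1
dme-miR-284-5p	2.4	0.4	0.6	0.1	0.0	G1
dme-miR-927-5p	2.1	-0.6	0.5	0.4	0.0	G1
dme-miR-87-3p	2.6	-0.3	0.7	0.0	-0.1	G1
dme-miR-281-3p	1.6	-0.2	-0.2	-0.7	-0.1	G1
dme-miR-1008-3p	1.4	-0.2	0.5	0.3	-0.5	G1
dme-miR-8-5p	1.1	-1.6	1.0	1.0	2.6	G1
dme-miR-10-3p	2.2	-1.0	0.6	1.2	2.0	G1
dme-miR-14-3p	1.0	-1.4	1.5	-0.3	1.1	G1
dme-miR-11-3p	0.8	1.3	0.8	0.5	2.4	G2
dme-miR-9b-5p	0.4	0.8	-0.4	-0.2	1.7	G2
dme-miR-1012-3p	-0.8	-0.8	-0.5	-1.0	1.4	G2
dme-miR-1010-3p	0.2	-0.6	0.4	0.5	1.4	G2
dme-miR-5-5p	0.6	1.4	1.2	1.3	1.2	G2
dme-miR-12-5p	0.3	0.4	0.6	1.2	1.1	G2
dme-miR-13a-3p	0.2	0.6	1.3	0.2	0.0	G2
dme-miR-31a-3p	0.2	0.0	1.0	0.7	-0.3	G2
dme-miR-124-3p	0.0	-0.3	1.2	0.2	-0.3	G2
dme-miR-965-5p	0.9	-0.4	0.7	0.8	0.8	G2
dme-miR-1003-3p	-0.8	-0.5	0.1	0.0	0.0	G2
dme-miR-190-5p	0.4	0.1	0.0	0.1	-0.7	G2
dme-miR-282-3p	-0.1	-1.9	-1.7	-0.7	-0.7	G2
dme-miR-2a-3p	0.6	0.2	0.8	0.5	-1.5	G2
dme-miR-33-5p	-0.3	-2.4	-1.6	-1.1	-1.9	G2
dme-miR-281-2-5p	-0.5	-1.3	0.3	-0.1	0.6	G2
dme-miR-2b-2-5p	-0.8	-1.6	0.5	1.0	0.5	G2
dme-miR-375-3p	0.1	-2.3	0.8	-0.2	0.1	G2
dme-miR-9a-5p	0.8	0.5	1.9	1.5	3.3	G2
dme-miR-3-5p	-2.8	0.0	-0.1	-0.1	0.0	G3
dme-miR-184-3p	-1.4	-0.2	0.1	0.0	0.9	G3
dme-miR-312-5p	-3.8	-0.2	-1.1	-0.6	-0.6	G3
dme-miR-6-1-5p	-4.2	-0.3	-0.7	-0.8	0.0	G3
dme-miR-3-3p	-1.8	-0.4	0.4	0.5	0.7	G3
dme-miR-999-3p	-1.7	-0.4	-0.2	-0.1	0.6	G3
dme-miR-305-3p	-1.0	-0.7	-0.2	-0.6	0.0	G3
dme-miR-9c-5p	-1.7	-0.8	-1.0	-1.0	0.0	G3
dme-miR-13b-2-5p	-1.4	-0.8	0.7	0.6	0.1	G3
dme-miR-9b-3p	-2.5	-1.1	0.0	-0.1	-0.3	G3
dme-miR-79-3p	-2.3	-1.1	-0.6	0.0	0.7	G3
dme-miR-92a-3p	-2.3	-1.3	0.3	-0.3	1.4	G3
dme-miR-124-5p	-1.5	-1.3	0.5	0.5	0.4	G3
dme-miR-1002-3p	-1.6	-1.6	0.3	0.2	0.0	G3
dme-miR-308-3p	-1.4	-1.7	-0.8	-0.1	-0.5	G3
dme-miR-310-3p	-3.0	-1.7	-1.4	-1.7	-0.3	G3
dme-miR-92b-3p	-2.5	-1.9	0.1	0.0	1.2	G3
dme-miR-968-3p	-2.1	-2.2	0.3	0.5	0.7	G3
dme-miR-995-3p	-1.4	-2.4	-0.1	-0.4	0.4	G3
dme-miR-312-3p	-5.2	-2.5	-1.2	-0.9	-0.2	G3
dme-miR-279-3p	-3.9	-2.6	0.3	0.0	0.8	G3
dme-miR-6-2-5p	-4.9	-2.7	-1.0	-0.1	0.4	G3
dme-miR-iab-8-3p	-2.3	-3.2	0.8	0.5	-0.3	G3
dme-miR-iab-4-5p	-2.3	-3.3	1.0	0.7	-0.3	G3
dme-miR-275-3p	-2.9	-3.6	-1.2	-1.4	0.2	G3
dme-miR-282-5p	-2.5	-3.7	-1.7	-1.2	-1.4	G3
dme-miR-311-3p	-5.2	-4.8	-1.2	-2.0	-0.2	G3
dme-miR-305-5p	-4.0	-4.9	-1.8	-1.8	-1.3	G3
dme-miR-306-5p	-5.1	-5.2	-0.6	-0.8	-1.1	G3
dme-miR-1-3p	-1.5	0.2	2.2	1.2	3.8	G4
dme-miR-988-3p	-1.0	-0.1	1.4	1.2	0.0	G4
dme-miR-4-3p	-1.1	-0.5	2.2	0.7	1.4	G4
dme-miR-31b-5p	-1.2	-0.9	0.1	-0.9	1.7	G4
dme-miR-981-3p	1.0	-1.9	-0.1	0.6	0.4	G4
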