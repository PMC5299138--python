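mirna	E60	E80	printed_fold	family	dcx_sites	lis1_sites
ssc-miR-10a-5p	35.3	165.9	4.7	miR-10-5p	0	0
ssc-miR-10b	230.1	957	4.2	miR-10-5p	0	0
ssc-miR-126-3p	434.6	1650.5	3.8	miR-126-3p.1	0	0
ssc-miR-129a-5p	30.7	144.2	4.7	miR-129-5p	1	0
ssc-miR-132	109	292.6	2.7	miR-132-3p/212-3p	0	0
ssc-miR-142-5p	47.2	130.4	2.8	miR-142-5p/5590-3p	0	0
ssc-miR-143-3p	8455.7	30879.9	3.7	miR-143-3p/4770/6088	1	0
ssc-miR-148a-3p	4189.3	12959.3	3.1	miR-148-3p/152-3p	0	0
ssc-miR-152	60.8	229.4	3.8	miR-148-3p/152-3p	0	0
ssc-miR-424-5p	20.3	106.8	5.2	miR-15-5p/16-5p/195-5p/424-5p/497-5p/6838-5p	0	3
ssc-miR-199a-3p	392.9	1486	3.8	miR-199-3p/3129-5p	0	0
ssc-miR-199a-5p	49.6	265.8	5.3	miR-199-5p	0	0
ssc-miR-204	361.8	41785.8	115.5	miR-204-5p/211-5p	2	0
ssc-miR-208b	11.3	150.7	13.3	miR-208-3p	0	0
ssc-miR-210	46.6	107.6	2.3	miR-210-3p	0	0
ssc-miR-218-5p	47.2	127.3	2.7	miR-218-5p	1	0
ssc-miR-23a	87.9	290.4	3.3	miR-23-3p/130a-5p	0	0
ssc-miR-24-3p	309.8	891.8	2.9	miR-24-3p	0	0
ssc-miR-363	874.3	1927.9	2.2	miR-25-3p/32-5p/92-3p/363-3p/367-3p	1	1
ssc-miR-92b-3p	5112.3	16944.1	3.3	miR-25-3p/32-5p/92-3p/363-3p/367-3p	1	1
ssc-miR-27a	168.7	545.1	3.2	miR-27-3p	2	0
ssc-miR-30a-5p	3517.8	8437.5	2.4	miR-30-5p	1	0
ssc-miR-30b-5p	179.3	771.6	4.3	miR-30-5p	1	0
ssc-miR-30c-5p	534.7	1612.1	3	miR-30-5p	1	0
ssc-miR-31	35.8	130.4	3.6	miR-31-5p	0	0
ssc-miR-328	30.7	104.5	3.4	miR-328-3p	0	0
ssc-miR-34a	2.3	122.5	50.2	miR-34-5p/449-5p	1	0
ssc-miR-34c	75.4	13591.4	180.1	miR-34-5p/449-5p	1	0
ssc-miR-378	320.8	989.3	3.1	miR-378-3p/422	1	0
ssc-miR-451	94.6	536.5	5.7	miR-451a	0	0
ssc-miR-486	1458.6	3540.6	2.4	miR-486-5p	0	0
ssc-miR-542-3p	15	183	12.1	miR-542-3p	1	0
ssc-miR-15a	746.7	344.9	-2.2	miR-15-5p/16-5p/195-5p/424-5p/497-5p/6838-5p	0	3
ssc-miR-16	15528.7	6901.3	-2.3	miR-15-5p/16-5p/195-5p/424-5p/497-5p/6838-5p	0	3
ssc-miR-17-5p	378.9	171.2	-2.2	miR-17-5p/20-5p/93-5p/106-5p/519-3p/526-3p	0	1
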