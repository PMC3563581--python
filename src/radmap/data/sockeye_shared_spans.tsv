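group	female_cM	male_cM
1	42.7	25
2	119.5	123
3	79.3	96.9
4	153.5	160.7
5	72	76.6
6	91.3	72.8
7a	6.9	6.3
7b	57.1	57.6
8	71.2	81.3
9	197.4	224.1
10	155.4	126.2
11	98.8	99.5
12	113.2	123
13	144.4	131.4
14	126.9	138.9
15	151.3	120.2
16	80.9	84.1
17	39.8	44.3
18	120.9	115
19	51.5	50.5
20	156.8	212.8
21	72.1	77.8
22	189	176.2
23	113.1	159.6
24	104.2	115.9
25	76.9	74.5
26	53.3	46.8
27	90.7	82.4
28	71.3	91.3
29	22.7	22.2
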