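# Five classic per-residue physicochemical scales (literature values):
# hydropathy: Kyte & Doolittle (1982); volume: Zamyatnin (1972) residue volume (A^3);
# beta_prop / helix_prop: Chou & Fasman (1978) conformational propensities;
# polarity: Grantham (1974).
aa	hydropathy	volume	beta_prop	helix_prop	polarity
A	1.8	88.6	0.83	1.42	8.1
C	2.5	108.5	1.19	0.70	5.5
D	-3.5	111.1	0.54	1.01	13.0
E	-3.5	138.4	0.37	1.51	12.3
F	2.8	189.9	1.38	1.13	5.2
G	-0.4	60.1	0.75	0.57	9.0
H	-3.2	153.2	0.87	1.00	10.4
I	4.5	166.7	1.60	1.08	5.2
K	-3.9	168.6	0.74	1.16	11.3
L	3.8	166.7	1.30	1.21	4.9
M	1.9	162.9	1.05	1.45	5.7
N	-3.5	114.1	0.89	0.67	11.6
P	-1.6	112.7	0.55	0.57	8.0
Q	-3.5	143.8	1.10	1.11	10.5
R	-4.5	173.4	0.93	0.98	10.5
S	-0.8	89.0	0.75	0.77	9.2
T	-0.7	116.1	1.19	0.83	8.6
V	4.2	140.0	1.70	1.06	5.9
W	-0.9	227.8	1.37	1.08	5.4
Y	-1.3	193.6	1.47	0.69	6.2
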