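# SYNTHETIC effective inter-residue contact energy table (not a published matrix).
# Constructed surrogate for a knowledge-based contact potential: an additive
# hydropathy form e(a,b) = -(0.15 + 0.05*(h_a + h_b)), h = Kyte-Doolittle (1982)
# hydropathy, rounded to 3 decimals. Symmetric; hydrophobic self-contacts are the
# most favorable, as in statistical contact potentials. Override with any
# whitespace-delimited 20x20 (or lower-triangle) matrix with a one-letter header row.
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.330	-0.365	-0.065	-0.065	-0.380	-0.220	-0.080	-0.465	-0.045	-0.430	-0.335	-0.065	-0.160	-0.065	-0.015	-0.200	-0.205	-0.450	-0.195	-0.175
C	-0.365	-0.400	-0.100	-0.100	-0.415	-0.255	-0.115	-0.500	-0.080	-0.465	-0.370	-0.100	-0.195	-0.100	-0.050	-0.235	-0.240	-0.485	-0.230	-0.210
D	-0.065	-0.100	0.200	0.200	-0.115	0.045	0.185	-0.200	0.220	-0.165	-0.070	0.200	0.105	0.200	0.250	0.065	0.060	-0.185	0.070	0.090
E	-0.065	-0.100	0.200	0.200	-0.115	0.045	0.185	-0.200	0.220	-0.165	-0.070	0.200	0.105	0.200	0.250	0.065	0.060	-0.185	0.070	0.090
F	-0.380	-0.415	-0.115	-0.115	-0.430	-0.270	-0.130	-0.515	-0.095	-0.480	-0.385	-0.115	-0.210	-0.115	-0.065	-0.250	-0.255	-0.500	-0.245	-0.225
G	-0.220	-0.255	0.045	0.045	-0.270	-0.110	0.030	-0.355	0.065	-0.320	-0.225	0.045	-0.050	0.045	0.095	-0.090	-0.095	-0.340	-0.085	-0.065
H	-0.080	-0.115	0.185	0.185	-0.130	0.030	0.170	-0.215	0.205	-0.180	-0.085	0.185	0.090	0.185	0.235	0.050	0.045	-0.200	0.055	0.075
I	-0.465	-0.500	-0.200	-0.200	-0.515	-0.355	-0.215	-0.600	-0.180	-0.565	-0.470	-0.200	-0.295	-0.200	-0.150	-0.335	-0.340	-0.585	-0.330	-0.310
K	-0.045	-0.080	0.220	0.220	-0.095	0.065	0.205	-0.180	0.240	-0.145	-0.050	0.220	0.125	0.220	0.270	0.085	0.080	-0.165	0.090	0.110
L	-0.430	-0.465	-0.165	-0.165	-0.480	-0.320	-0.180	-0.565	-0.145	-0.530	-0.435	-0.165	-0.260	-0.165	-0.115	-0.300	-0.305	-0.550	-0.295	-0.275
M	-0.335	-0.370	-0.070	-0.070	-0.385	-0.225	-0.085	-0.470	-0.050	-0.435	-0.340	-0.070	-0.165	-0.070	-0.020	-0.205	-0.210	-0.455	-0.200	-0.180
N	-0.065	-0.100	0.200	0.200	-0.115	0.045	0.185	-0.200	0.220	-0.165	-0.070	0.200	0.105	0.200	0.250	0.065	0.060	-0.185	0.070	0.090
P	-0.160	-0.195	0.105	0.105	-0.210	-0.050	0.090	-0.295	0.125	-0.260	-0.165	0.105	0.010	0.105	0.155	-0.030	-0.035	-0.280	-0.025	-0.005
Q	-0.065	-0.100	0.200	0.200	-0.115	0.045	0.185	-0.200	0.220	-0.165	-0.070	0.200	0.105	0.200	0.250	0.065	0.060	-0.185	0.070	0.090
R	-0.015	-0.050	0.250	0.250	-0.065	0.095	0.235	-0.150	0.270	-0.115	-0.020	0.250	0.155	0.250	0.300	0.115	0.110	-0.135	0.120	0.140
S	-0.200	-0.235	0.065	0.065	-0.250	-0.090	0.050	-0.335	0.085	-0.300	-0.205	0.065	-0.030	0.065	0.115	-0.070	-0.075	-0.320	-0.065	-0.045
T	-0.205	-0.240	0.060	0.060	-0.255	-0.095	0.045	-0.340	0.080	-0.305	-0.210	0.060	-0.035	0.060	0.110	-0.075	-0.080	-0.325	-0.070	-0.050
V	-0.450	-0.485	-0.185	-0.185	-0.500	-0.340	-0.200	-0.585	-0.165	-0.550	-0.455	-0.185	-0.280	-0.185	-0.135	-0.320	-0.325	-0.570	-0.315	-0.295
W	-0.195	-0.230	0.070	0.070	-0.245	-0.085	0.055	-0.330	0.090	-0.295	-0.200	0.070	-0.025	0.070	0.120	-0.065	-0.070	-0.315	-0.060	-0.040
Y	-0.175	-0.210	0.090	0.090	-0.225	-0.065	0.075	-0.310	0.110	-0.275	-0.180	0.090	-0.005	0.090	0.140	-0.045	-0.050	-0.295	-0.040	-0.020
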