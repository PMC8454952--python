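# residue-pair direct-contact well depths, kcal/mol (negative = favorable)
res	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.490	-0.517	-0.284	-0.284	-0.529	-0.404	-0.296	-0.595	-0.268	-0.568	-0.494	-0.284	-0.358	-0.284	-0.245	-0.389	-0.393	-0.583	-0.385	-0.369
C	-0.517	-0.544	-0.311	-0.311	-0.556	-0.432	-0.323	-0.622	-0.296	-0.595	-0.521	-0.311	-0.385	-0.311	-0.272	-0.416	-0.420	-0.611	-0.412	-0.397
D	-0.284	-0.311	0.372	0.372	-0.323	-0.198	-0.314	-0.389	-0.512	-0.362	-0.288	-0.078	-0.152	-0.078	-0.489	-0.183	-0.187	-0.377	-0.179	-0.163
E	-0.284	-0.311	0.372	0.372	-0.323	-0.198	-0.314	-0.389	-0.512	-0.362	-0.288	-0.078	-0.152	-0.078	-0.489	-0.183	-0.187	-0.377	-0.179	-0.163
F	-0.529	-0.556	-0.323	-0.323	-0.568	-0.443	-0.334	-0.634	-0.307	-0.607	-0.533	-0.323	-0.397	-0.323	-0.284	-0.428	-0.432	-0.622	-0.424	-0.408
G	-0.404	-0.432	-0.198	-0.198	-0.443	-0.319	-0.210	-0.509	-0.183	-0.482	-0.408	-0.198	-0.272	-0.198	-0.159	-0.303	-0.307	-0.498	-0.299	-0.284
H	-0.296	-0.323	-0.314	-0.314	-0.334	-0.210	0.011	-0.401	0.151	-0.373	-0.299	-0.089	-0.163	-0.089	0.174	-0.194	-0.198	-0.389	-0.191	-0.175
I	-0.595	-0.622	-0.389	-0.389	-0.634	-0.509	-0.401	-0.700	-0.373	-0.673	-0.599	-0.389	-0.463	-0.389	-0.350	-0.494	-0.498	-0.688	-0.490	-0.474
K	-0.268	-0.296	-0.512	-0.512	-0.307	-0.183	0.151	-0.373	0.403	-0.346	-0.272	-0.062	-0.136	-0.062	0.427	-0.167	-0.171	-0.362	-0.163	-0.148
L	-0.568	-0.595	-0.362	-0.362	-0.607	-0.482	-0.373	-0.673	-0.346	-0.646	-0.572	-0.362	-0.436	-0.362	-0.323	-0.467	-0.471	-0.661	-0.463	-0.447
M	-0.494	-0.521	-0.288	-0.288	-0.533	-0.408	-0.299	-0.599	-0.272	-0.572	-0.498	-0.288	-0.362	-0.288	-0.249	-0.393	-0.397	-0.587	-0.389	-0.373
N	-0.284	-0.311	-0.078	-0.078	-0.323	-0.198	-0.089	-0.389	-0.062	-0.362	-0.288	-0.078	-0.152	-0.078	-0.039	-0.183	-0.187	-0.377	-0.179	-0.163
P	-0.358	-0.385	-0.152	-0.152	-0.397	-0.272	-0.163	-0.463	-0.136	-0.436	-0.362	-0.152	-0.226	-0.152	-0.113	-0.257	-0.261	-0.451	-0.253	-0.237
Q	-0.284	-0.311	-0.078	-0.078	-0.323	-0.198	-0.089	-0.389	-0.062	-0.362	-0.288	-0.078	-0.152	-0.078	-0.039	-0.183	-0.187	-0.377	-0.179	-0.163
R	-0.245	-0.272	-0.489	-0.489	-0.284	-0.159	0.174	-0.350	0.427	-0.323	-0.249	-0.039	-0.113	-0.039	0.450	-0.144	-0.148	-0.338	-0.140	-0.124
S	-0.389	-0.416	-0.183	-0.183	-0.428	-0.303	-0.194	-0.494	-0.167	-0.467	-0.393	-0.183	-0.257	-0.183	-0.144	-0.288	-0.292	-0.482	-0.284	-0.268
T	-0.393	-0.420	-0.187	-0.187	-0.432	-0.307	-0.198	-0.498	-0.171	-0.471	-0.397	-0.187	-0.261	-0.187	-0.148	-0.292	-0.296	-0.486	-0.288	-0.272
V	-0.583	-0.611	-0.377	-0.377	-0.622	-0.498	-0.389	-0.688	-0.362	-0.661	-0.587	-0.377	-0.451	-0.377	-0.338	-0.482	-0.486	-0.677	-0.478	-0.463
W	-0.385	-0.412	-0.179	-0.179	-0.424	-0.299	-0.191	-0.490	-0.163	-0.463	-0.389	-0.179	-0.253	-0.179	-0.140	-0.284	-0.288	-0.478	-0.280	-0.264
Y	-0.369	-0.397	-0.163	-0.163	-0.408	-0.284	-0.175	-0.474	-0.148	-0.447	-0.373	-0.163	-0.237	-0.163	-0.124	-0.268	-0.272	-0.463	-0.264	-0.249
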