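# UFF atomic parameters (Rappe-type universal force field).
# columns: type  r1[A]  theta0[deg]  x1[A]  D1[kcal/mol]  zeta  Z1  V_sp3[kcal/mol]  U_sp2  chi[GMP electronegativity]
type	r1	theta0	x1	D1	zeta	Z1	V	U	chi
H_	0.354	180.0	2.886	0.044	12.0	0.712	0.0	0.0	4.528
He4+4	0.849	90.0	2.362	0.056	15.24	0.098	0.0	0.0	9.66
Li	1.336	180.0	2.451	0.025	12.0	1.026	0.0	2.0	3.006
Be3+2	1.074	109.47	2.745	0.085	12.0	1.565	0.0	2.0	4.877
B_3	0.838	109.47	4.083	0.180	12.052	1.755	0.0	2.0	5.11
B_2	0.828	120.0	4.083	0.180	12.052	1.755	0.0	2.0	5.11
C_3	0.757	109.47	3.851	0.105	12.73	1.912	2.119	2.0	5.343
C_R	0.729	120.0	3.851	0.105	12.73	1.912	0.0	2.0	5.343
C_2	0.732	120.0	3.851	0.105	12.73	1.912	0.0	2.0	5.343
C_1	0.706	180.0	3.851	0.105	12.73	1.912	0.0	2.0	5.343
N_3	0.700	106.7	3.660	0.069	13.407	2.544	0.450	2.0	6.899
N_R	0.699	120.0	3.660	0.069	13.407	2.544	0.0	2.0	6.899
N_2	0.685	111.2	3.660	0.069	13.407	2.544	0.0	2.0	6.899
N_1	0.656	180.0	3.660	0.069	13.407	2.544	0.0	2.0	6.899
O_3	0.658	104.51	3.500	0.060	14.085	2.300	0.018	2.0	8.741
O_3_z	0.528	146.0	3.500	0.060	14.085	2.300	0.018	2.0	8.741
O_R	0.680	110.0	3.500	0.060	14.085	2.300	0.0	2.0	8.741
O_2	0.634	120.0	3.500	0.060	14.085	2.300	0.0	2.0	8.741
O_1	0.639	180.0	3.500	0.060	14.085	2.300	0.0	2.0	8.741
F_	0.668	180.0	3.364	0.050	14.762	1.735	0.0	2.0	10.874
Ne4+4	0.920	90.0	3.243	0.042	15.440	0.194	0.0	2.0	11.04
Na	1.539	180.0	2.983	0.030	12.0	1.081	0.0	1.25	2.843
Mg3+2	1.421	109.47	3.021	0.111	12.0	1.787	0.0	1.25	3.951
Al3	1.244	109.47	4.499	0.505	11.278	1.792	0.0	1.25	4.06
Si3	1.117	109.47	4.295	0.402	12.175	2.323	1.225	1.25	4.168
P_3+3	1.101	93.8	4.147	0.305	13.072	2.863	2.400	1.25	5.463
P_3+5	1.056	109.47	4.147	0.305	13.072	2.863	2.400	1.25	5.463
S_3+2	1.064	92.1	4.035	0.274	13.969	2.703	0.484	1.25	6.928
S_3+4	1.049	103.20	4.035	0.274	13.969	2.703	0.484	1.25	6.928
S_3+6	1.027	109.47	4.035	0.274	13.969	2.703	0.484	1.25	6.928
S_R	1.077	92.2	4.035	0.274	13.969	2.703	0.0	1.25	6.928
S_2	0.854	120.0	4.035	0.274	13.969	2.703	0.0	1.25	6.928
Cl	1.044	180.0	3.947	0.227	14.866	2.348	0.0	1.25	8.564
Ar4+4	1.032	90.0	3.868	0.185	15.763	0.300	0.0	1.25	9.465
K_	1.953	180.0	3.812	0.035	12.0	1.165	0.0	0.7	2.421
Ca6+2	1.761	90.0	3.399	0.238	12.0	2.141	0.0	0.7	3.231
Mn6+2	1.382	90.0	2.961	0.013	12.0	2.430	0.0	0.7	3.325
Fe3+2	1.270	109.47	4.540	0.013	12.0	2.609	0.0	0.7	3.76
Fe6+2	1.335	90.0	4.540	0.013	12.0	2.609	0.0	0.7	3.76
Co6+3	1.241	90.0	2.872	0.014	12.0	2.430	0.0	0.7	4.105
Ni4+2	1.164	90.0	2.834	0.015	12.0	2.430	0.0	0.7	4.465
Cu3+1	1.302	109.47	3.495	0.005	12.0	1.756	0.0	0.7	4.20
Zn3+2	1.193	109.47	4.045	0.124	12.0	1.308	0.0	0.7	5.106
Se3+2	1.190	90.6	4.205	0.291	15.105	2.754	0.335	0.7	6.428
Br	1.192	180.0	4.189	0.251	15.432	2.519	0.0	0.7	7.790
I_	1.382	180.0	4.500	0.339	15.497	2.650	0.0	0.2	6.822
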