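ligand	residue	e_es	e_ex	e_ct_mix	e_disp	g_sol	e_tot
3	GLU885	-4.290	0.830	-1.320	-2.070	1.890	-4.960
9	GLU885	-6.280	1.730	-1.720	-2.550	1.310	-7.520
8	GLU885	1.090	4.550	-1.880	-2.670	-2.400	-3.490
7	CYS919	-3.770	4.350	-2.610	-4.480	-0.790	-7.300
9	CYS919	-2.770	15.290	-1.870	-4.700	0.160	6.110
6	LYS838	-4.520	0.030	-0.630	-0.500	0.830	-4.790
2	LYS838	-1.660	0.002	-0.080	-0.200	-1.100	-3.050
2	LYS868	-6.450	7.770	-2.320	-6.860	1.470	-6.380
8	LYS868	-2.920	3.370	-1.720	-5.940	5.060	-2.150
8	ALA866	1.020	2.480	-1.100	-2.950	0.340	-0.220
9	ALA866	-0.670	1.220	-0.690	-3.220	0.340	-3.030
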