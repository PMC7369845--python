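ligand	residue	e_elst	e_exch	e_ind	e_disp	e_total
8	ALA866	-5.320	5.670	-1.480	-5.140	-6.270
9	CYS919	-0.040	14.400	-3.110	-5.780	5.470
7	CYS919	-4.920	5.800	-2.570	-4.020
8	GLU885	6.230	16.480	-8.340	-4.130	10.230
3	GLU885	-0.690	2.260	-0.930	-2.310
6	PHE918	-3.830	11.340	-1.580	-9.600
8	PHE918	-0.490	2.810	-0.290	-2.860
7	PHE1047	-8.120	19.980	-2.350	-19.460
9	PHE1047	-1.630	12.680	-1.940	-8.040
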