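gene_id	logfc	pvalue	fdr	gene_name
ENSG00000185567	2.176849204	5.15E-299	2.25E-295	AHNAK2
ENSG00000132821	2.080483757	2.77E-280	9.09E-277	VSTM2L
ENSG00000117984	1.586454466	3.61E-273	9.49E-270	CTSD
ENSG00000039139	1.913971451	1.13E-234	1.49E-231	DNAH5
ENSG00000163083	1.827194971	3.38E-216	4.03E-213	INHBB
ENSG00000184371	1.564908962	9.87E-215	1.08E-211	CSF1
ENSG00000170373	1.445267367	7.43E-214	7.51E-211	CST1
ENSG00000183018	2.687264202	2.37E-207	2.22E-204	SPNS2
ENSG00000148180	1.25021061	1.35E-204	1.18E-201	GSN
ENSG00000187678	1.29153331	2.72E-191	2.23E-188	SPRY4
ENSG00000109062	1.468364079	5.45E-183	3.97E-180	SLC9A3R1
ENSG00000124766	1.897033792	1.36E-178	9.39E-176	SOX4
ENSG00000100994	1.081533166	2.15E-168	1.35E-165	PYGB
ENSG00000181634	1.433165343	1.64E-154	8.26E-152	TNFSF15
ENSG00000147676	1.792602889	2.15E-153	1.05E-150	MAL2
ENSG00000107819	1.097217673	1.35E-152	6.33E-150	SFXN3
ENSG00000167644	1.245454774	2.18E-150	9.88E-148	C19orf33
ENSG00000172794	2.37902321	3.41E-147	1.49E-144	RAB37
ENSG00000058085	1.09085532	1.15E-145	4.88E-143	LAMC2
ENSG00000175130	1.074875932	2.20E-139	9.03E-137	MARCKSL1
ENSG00000171345	1.019257679	8.08E-137	3.12E-134	KRT19
ENSG00000167552	1.388799485	1.60E-136	5.82E-134	TUBA1A
ENSG00000132470	1.437708599	1.07E-135	3.79E-133	ITGB4
ENSG00000008513	1.019331762	3.84E-133	1.29E-130	ST3GAL1
ENSG00000167642	0.963304201	1.10E-126	3.43E-124	SPINT2
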