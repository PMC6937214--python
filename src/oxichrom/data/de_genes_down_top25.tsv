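gene_id	logfc	pvalue	fdr	gene_name
ENSG00000134013	-3.053434126	0	0	LOXL2
ENSG00000122545	-1.493781116	6.6E-272	1.45E-268	SEP-T7
ENSG00000137801	-1.65563595	1.11E-262	2.08E-259	THBS1
ENSG00000112062	-1.367605967	1.43E-252	2.34E-249	MAPK14
ENSG00000146281	-1.644281336	6.67E-244	9.73E-241	PM20D2
ENSG00000105971	-1.358844865	4.29E-189	3.31E-186	CAV2
ENSG00000117500	-1.227263597	2.54E-176	1.67E-173	TMED5
ENSG00000172380	-1.135404374	1.81E-162	1.08E-159	GNG12
ENSG00000152558	-1.10232016	1.28E-160	7.33E-158	TMEM123
ENSG00000100462	-1.134694357	2.31E-160	1.26E-157	PRMT5
ENSG00000213281	-1.098589526	6.65E-160	3.49E-157	NRAS
ENSG00000162521	-1.195180927	7.41E-138	2.95E-135	RBBP4
ENSG00000196396	-1.038088551	1.5E-136	5.64E-134	PTPN1
ENSG00000182400	-1.288279943	9.25E-134	3.2E-131	TRAPPC6B
ENSG00000115339	-1.421874178	1.01E-132	3.31E-130	GALNT3
ENSG00000105810	-1.03878264	1.67E-132	5.35E-130	CDK6
ENSG00000105849	-1.177181646	7.96E-125	2.38E-122	TWISTNB
ENSG00000176853	-0.991116504	4.73E-124	1.38E-121	FAM91A1
ENSG00000113742	-1.271922708	3.08E-120	8.43E-118	CPEB4
ENSG00000156017	-1.215741594	1.39E-117	3.52E-115	CARNMT1
ENSG00000154429	-1.346899288	2.62E-117	6.5E-115	CCSAP
ENSG00000101974	-1.060939839	1.68E-116	4.02E-114	ATP11C
ENSG00000073712	-0.991731657	6.59E-116	1.54E-113	FERMT2
ENSG00000162104	-1.444767007	1.64E-113	3.77E-111	ADCY9
ENSG00000064042	-1.111524916	1.06E-110	2.36E-108	LIMCH1
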