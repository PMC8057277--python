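cancer_type	abbreviation	median_pfs_months	pfs_threshold_months	n_included	n_above	n_below
Adrenocortical Carcinoma	ADCC	27.60	24	85	46	39
Glioblastoma Multiforme	BGBM	5.92	6	306	161	145
Bladder Urothelial Carcinoma	BLCA	17.98	18	291	157	134
Brain Lower Grade Glioma	BLGG	27.81	24	290	168	122
Breast Invasive Carcinoma	BRCA	46.62	60	321	211	110
Cervical Squamous Cell Carcinoma	CESC	31.27	30	134	79	55
Cholangiocarcinoma	CHOL	7.96	9	32	18	14
Colorectal Adenocarcinoma	COAD	29.06	24	310	202	108
Diffuse Large B-Cell Lymphoma	DLBC	32.01	30	20	14	6
Esophageal Adenocarcinoma	ESCA	10.55	12	141	83	58
Head and Neck Squamous Cell Carcinoma	HNSC	25.97	24	351	190	161
Kidney Chromophobe	KICH	87.24	60	45	37	8
Kidney Renal Clear Cell Carcinoma	KIRC	45.96	48	264	200	64
Kidney Renal Papillary Cell Carcinoma	KIRP	34.29	36	166	127	39
Liver Hepatocellular Carcinoma	LIHC	12.89	12	254	122	132
Lung Adenocarcinoma	LUAD	23.87	24	320	163	157
Lung Squamous Cell Carcinoma	LUSC	31.56	36	283	188	95
Mesothelioma	MESO	12.00	12	64	16	48
Ovarian Serous Cystadenocarcinoma	OVCA	16.04	18	294	137	157
Pancreatic Adenocarcinoma	PAAD	12.33	12	161	130	31
Prostate Adenocarcinoma	PRAD	37.00	36	222	156	66
Sarcoma	SARC	17.80	18	202	128	74
Skin Cutaneous Melanoma	SKCM	28.59	30	371	219	152
Stomach Adenocarcinoma	STAD	16.57	18	264	145	119
Testicular Germ Cell Tumors	TGCT	40.01	42	73	46	27
Thyroid Carcinoma	THCA	39.73	36	217	175	42
Thymoma	THYM	45.63	48	62	44	18
Uterine Corpus Endometrial Carcinoma	UCEC	35.13	36	257	161	96
Uterine Carcinosarcoma	UCSA	11.64	12	51	28	23
Uveal Melanoma	UVME	27.52	24	52	34	18
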