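uniprot_id	gene_name	protein_name	motive_id	is_effector	ann_score
P08123	COL1A2	Collagen alpha-2(I) chain	myocardial_fibrosis	True	92.52
P08123	COL1A2	Collagen alpha-2(I) chain	inflammation	False	90.86
P08123	COL1A2	Collagen alpha-2(I) chain	endothelial_dysfunction	True	87.50
P08123	COL1A2	Collagen alpha-2(I) chain	das_general	True	69.82
P35625	TIMP3	Metalloproteinase inhibitor 3	endothelial_dysfunction	True	91.85
P35625	TIMP3	Metalloproteinase inhibitor 3	das_general	True	82.53
P35625	TIMP3	Metalloproteinase inhibitor 3	calcification	False	69.20
P35625	TIMP3	Metalloproteinase inhibitor 3	raa_system	False	63.61
P02461	COL3A1	Collagen alpha-1(III) chain	myocardial_fibrosis	True	91.69
P02461	COL3A1	Collagen alpha-1(III) chain	endothelial_dysfunction	True	87.29
P02461	COL3A1	Collagen alpha-1(III) chain	das_general	True	76.47
P01033	TIMP1	Metalloproteinase inhibitor 1	endothelial_dysfunction	True	91.45
P01033	TIMP1	Metalloproteinase inhibitor 1	das_general	True	84.60
P01033	TIMP1	Metalloproteinase inhibitor 1	calcification	False	68.80
P01042	KNG1	Kininogen-1	das_general	True	90.45
P01042	KNG1	Kininogen-1	inflammation	True	87.34
P01042	KNG1	Kininogen-1	raa_system	False	70.10
P01042	KNG1	Kininogen-1	calcification	False	63.40
P05231	IL6	Interleukin-6	myocardial_fibrosis	True	90.45
P05231	IL6	Interleukin-6	calcification	True	88.05
P05231	IL6	Interleukin-6	inflammation	True	87.64
P05231	IL6	Interleukin-6	das_general	True	73.24
P07339	CTSD	Cathepsin D	das_general	True	87.00
P07339	CTSD	Cathepsin D	endothelial_dysfunction	True	84.46
P07339	CTSD	Cathepsin D	hypertrophy	False	71.66
P21810	BGN	Biglycan	inflammation	True	86.97
P21810	BGN	Biglycan	calcification	False	84.26
P21810	BGN	Biglycan	myocardial_fibrosis	False	83.08
P21810	BGN	Biglycan	das_general	True	80.74
P21810	BGN	Biglycan	endothelial_dysfunction	False	78.98
P21810	BGN	Biglycan	lipoprotein_accumulation	False	70.50
P14625	HSP90B1	Endoplasmin	inflammation	False	86.48
P14625	HSP90B1	Endoplasmin	endothelial_dysfunction	False	74.62
P14625	HSP90B1	Endoplasmin	das_general	False	70.58
P14625	HSP90B1	Endoplasmin	lipoprotein_accumulation	False	65.44
P01019	AGT	Angiotensinogen	das_general	True	84.81
P01019	AGT	Angiotensinogen	myocardial_fibrosis	True	82.54
P01019	AGT	Angiotensinogen	hypertrophy	True	78.60
P01019	AGT	Angiotensinogen	raa_system	True	65.54
P08253	MMP2	72 kDa type IV collagenase	calcification	True	84.40
P08253	MMP2	72 kDa type IV collagenase	endothelial_dysfunction	True	75.40
P08253	MMP2	72 kDa type IV collagenase	myocardial_fibrosis	True	74.10
P08253	MMP2	72 kDa type IV collagenase	das_general	True	73.98
P08253	MMP2	72 kDa type IV collagenase	hypertrophy	False	71.88
P08253	MMP2	72 kDa type IV collagenase	oxidative_stress	False	64.52
P02766	TTR	Transthyretin	oxidative_stress	False	79.18
P02766	TTR	Transthyretin	inflammation	False	74.11
P02766	TTR	Transthyretin	das_general	False	71.21
P00441	SOD1	Superoxide dismutase [Cu-Zn]	inflammation	False	78.56
P00441	SOD1	Superoxide dismutase [Cu-Zn]	das_general	True	74.41
P00441	SOD1	Superoxide dismutase [Cu-Zn]	oxidative_stress	True	69.12
P10909	CLU	Clusterin	inflammation	False	76.50
P10909	CLU	Clusterin	endothelial_dysfunction	False	67.68
P10909	CLU	Clusterin	lipoprotein_accumulation	False	64.01
P07996	THBS1	Thrombospondin-1	endothelial_dysfunction	False	76.17
P07996	THBS1	Thrombospondin-1	myocardial_fibrosis	False	71.70
P07996	THBS1	Thrombospondin-1	raa_system	False	63.52
P02768	ALB	Serum albumin	inflammation	False	76.03
P02768	ALB	Serum albumin	endothelial_dysfunction	False	75.65
P02768	ALB	Serum albumin	hypertrophy	False	68.55
P02768	ALB	Serum albumin	lipoprotein_accumulation	False	68.34
Q00653	NFKB2	Nuclear factor NF-kappa-B p100 subunit	inflammation	True	75.62
Q00653	NFKB2	Nuclear factor NF-kappa-B p100 subunit	calcification	True	74.83
Q00653	NFKB2	Nuclear factor NF-kappa-B p100 subunit	das_general	True	72.15
P04114	APOB	Apolipoprotein B-100	endothelial_dysfunction	False	75.04
P04114	APOB	Apolipoprotein B-100	inflammation	False	74.02
P04114	APOB	Apolipoprotein B-100	das_general	True	71.61
P04114	APOB	Apolipoprotein B-100	lipoprotein_accumulation	True	64.60
P02647	APOA1	Apolipoprotein A-I	das_general	True	74.73
P02647	APOA1	Apolipoprotein A-I	endothelial_dysfunction	False	72.41
P02647	APOA1	Apolipoprotein A-I	lipoprotein_accumulation	True	64.68
P07585	DCN	Decorin	calcification	False	74.42
P07585	DCN	Decorin	endothelial_dysfunction	False	73.11
P07585	DCN	Decorin	hypertrophy	False	71.71
P07585	DCN	Decorin	myocardial_fibrosis	False	68.53
Q92743	HTRA1	Serine protease HTRA1	myocardial_fibrosis	False	72.82
Q92743	HTRA1	Serine protease HTRA1	endothelial_dysfunction	False	72.73
Q92743	HTRA1	Serine protease HTRA1	das_general	False	70.23
P01023	A2M	Alpha-2-macroglobulin	oxidative_stress	False	72.55
P01023	A2M	Alpha-2-macroglobulin	myocardial_fibrosis	False	70.52
P01023	A2M	Alpha-2-macroglobulin	inflammation	False	68.56
P01023	A2M	Alpha-2-macroglobulin	endothelial_dysfunction	False	68.30
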