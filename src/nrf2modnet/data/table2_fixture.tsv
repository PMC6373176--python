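compound	eig_144	sig_144	eig_192	sig_192	eig_224	sig_224	eig_325	sig_325	drug	dili_concern	reactivity
Allyl alcohol	4.2	1	2.3	1	2.7	1	2.2	1	0	absent	reactive
Azathioprine	5.2	1	2.8	1	5.7	1	6.4	1	1	most	reactive
Butylated hydroxyanisole	5.0	1	5.8	1	2.2	1	4.2	1	0	absent	bioactivated
Diethyl maleate	4.5	1	2.7	1	3.2	1	7.6	1	0	absent	reactive
Furosemide	3.2	1	3.2	1	2.1	1	3.8	1	1	ambiguous	bioactivated
Lomustine	2.2	1	2.7	1	2.5	1	3.8	1	1	less_none	reactive
Nitrofurantoin	6.3	1	5.1	1	3.2	1	2.5	1	1	most	bioactivated
Nitrofurazone	3.0	1	2.1	1	3.9	1	4.9	1	1	absent	not_bioactivated_or_reactive
Phorone	2.6	1	2.3	1	2.2	1	3.6	1	0	absent	reactive
Propylthiouracil	5.5	1	3.8	1	4.5	1	3.9	1	1	most	reactive
Acetaminophen	7.9	1	3.0	1	1.8	0	2.9	1	1	most	bioactivated
Benzbromarone	4.7	1	2.7	1	2.6	1	0.2	0	1	most	bioactivated
Bromoethylamine	0.5	0	2.4	1	4.4	1	3.6	1	0	absent	bioactivated
Danazol	2.5	1	2.5	1	2.1	1	0.3	0	1	most	bioactivated
Diclofenac	4.9	1	3.7	1	2.5	1	1.5	0	1	most	bioactivated
Doxorubicin	-0.2	0	6.3	1	3.6	1	2.0	1	1	less_none	bioactivated
Galactosamine	0.6	0	3.7	1	2.7	1	2.8	1	0	absent	unknown
Methylene dianiline	2.9	1	2.8	1	3.6	1	0.7	0	0	absent	bioactivated
N-methyl-n-nitrosourea	2.2	1	3.4	1	2.4	1	1.0	0	0	absent	reactive
Omeprazole	7.2	1	4.7	1	3.5	1	1.4	0	1	less_none	bioactivated
Phalloidin	0.5	0	2.1	1	2.0	1	2.0	1	0	absent	unknown
Phenobarbital	2.3	1	3.1	1	4.7	1	1.4	0	1	less_none	not_bioactivated_or_reactive
Tunicamycin	2.5	1	4.0	1	1.5	0	4.1	1	0	absent	unknown
Valproic acid	2.1	1	2.0	1	2.8	1	1.5	0	1	most	bioactivated
2,4-Dinitrophenol	2.0	0	2.2	1	2.7	1	0.0	0	0	absent	bioactivated
Adapin	3.0	1	0.7	0	2.6	1	0.2	0	1	less_none	unknown
Aflatoxin B1	-0.7	0	3.5	1	3.5	1	1.2	0	0	absent	bioactivated
Coumarin	3.3	1	1.6	0	2.0	0	2.6	1	1	absent	bioactivated
Diazepam	5.1	1	2.9	1	0.1	0	0.1	0	1	ambiguous	bioactivated
Flutamide	3.3	1	2.5	1	0.9	0	0.3	0	1	most	bioactivated
Ketoconazole	3.3	1	2.4	1	1.6	0	0.4	0	1	most	bioactivated
Naphthyl isothiocyanate	4.6	1	2.6	1	2.0	0	2.0	0	0	absent	reactive
Nefazodone	0.1	0	4.4	1	2.1	1	-0.1	0	1	most	bioactivated
Rosiglitazone maleate	2.5	1	2.5	1	0.6	0	-0.3	0	1	less_none	bioactivated
Sulindac	2.2	1	2.4	1	-0.3	0	-1.1	0	1	most	bioactivated
Colchicine	2.4	1	1.5	0	-2.0	0	-1.3	0	1	ambiguous	bioactivated
Dantrolene	0.1	0	-0.3	0	1.2	0	2.9	1	1	most	not_bioactivated_or_reactive
Enalapril	1.9	0	1.1	0	1.3	0	3.2	1	1	less_none	bioactivated
Isoniazid	2.0	1	0.1	0	1.3	0	0.0	0	1	most	bioactivated
Labetalol	2.0	1	0.9	0	1.6	0	1.1	0	1	most	not_bioactivated_or_reactive
Methapyrilene	4.5	1	1.2	0	0.2	0	0.5	0	1	absent	bioactivated
Methimazole	2.5	1	1.1	0	0.0	0	0.3	0	1	most	bioactivated
Moxisylyte	2.4	1	1.6	0	1.0	0	1.8	0	1	most	unknown
Papaverine	0.4	0	3.2	1	0.6	0	-0.1	0	1	most	unknown
Perhexiline	2.2	1	0.9	0	1.2	0	0.6	0	1	most	unknown
Phenylbutazone	1.7	0	2.1	1	0.4	0	0.2	0	1	absent	bioactivated
Ranitidine	2.3	1	-0.3	0	0.2	0	0.8	0	1	less_none	bioactivated
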