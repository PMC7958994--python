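trait	category
LDL cholesterol	lipid or lipoprotein measurement
HDL cholesterol	lipid or lipoprotein measurement
Triglycerides	lipid or lipoprotein measurement
Total cholesterol	lipid or lipoprotein measurement
Lipoprotein(a) levels	lipid or lipoprotein measurement
Rheumatoid arthritis	immune system disorder
Systemic lupus erythematosus	immune system disorder
Primary biliary cirrhosis	immune system disorder
Multiple sclerosis	immune system disorder
Alanine aminotransferase levels	liver enzyme measurement
Aspartate aminotransferase levels	liver enzyme measurement
Gamma glutamyl transferase levels	liver enzyme measurement
Crohn's disease	digestive system disorder
Ulcerative colitis	digestive system disorder
Inflammatory bowel disease	digestive system disorder
Coronary artery disease	cardiovascular disease
Myocardial infarction	cardiovascular disease
Atrial fibrillation	cardiovascular disease
Hepatocellular carcinoma	cancer
Breast cancer	cancer
Prostate cancer	cancer
Type 2 diabetes	metabolic disorder
Fasting glucose	metabolic disorder
Gout	metabolic disorder
Alzheimer's disease	neurological disorder
Parkinson's disease	neurological disorder
Schizophrenia	psychiatric disorder
Major depressive disorder	psychiatric disorder
Body mass index	body measurement
Height	body measurement
Waist-to-hip ratio	body measurement
Platelet count	hematological measurement
Red blood cell count	hematological measurement
C-reactive protein levels	inflammatory measurement
IL-6 levels	inflammatory measurement
Chronic kidney disease	kidney disease
Glomerular filtration rate	kidney disease
Asthma	respiratory disease
Chronic obstructive pulmonary disease	respiratory disease
Warfarin maintenance dose	drug response
Clopidogrel response	drug response
Bone mineral density	bone measurement
Heel bone mineral density	bone measurement
Urate levels	other measurement
Vitamin D levels	other measurement
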