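disease_name,category,country,sex_subset,n_pairs_total,n_concordant,n_discordant
Bladder cancer,cancer,"Sweden, Denmark, Finland",both,15668,5,189
Breast cancer (female),cancer,"Sweden, Denmark, Finland",female,8437,42,505
Colorectal cancer,cancer,"Sweden, Denmark, Finland",both,15668,30,416
Leukemia,cancer,"Sweden, Denmark, Finland",both,15668,2,103
Lung cancer,cancer,"Sweden, Denmark, Finland",both,15668,18,296
Ovarian cancer (female),cancer,"Sweden, Denmark, Finland",female,8437,3,125
Pancreatic cancer,cancer,"Sweden, Denmark, Finland",both,15668,3,123
Prostate cancer (male),cancer,"Sweden, Denmark, Finland",male,7231,40,299
Stomach cancer,cancer,"Sweden, Denmark, Finland",both,15668,11,223
Thyroid autoimmunity,autoimmune,Denmark,both,284,7,17
Type 1 diabetes,autoimmune,Finland,both,4307,3,20
Type 2 diabetes,obesity-associated,Finland,both,4307,29,113
Gallstone disease,obesity-associated,Sweden,both,11073,112,956
Alzheimer's disease,neurological,Sweden,both,398,2,8
Dementia,neurological,Sweden,both,398,3,16
Chronic fatigue,other,Sweden,both,3229,181,792
Gastroesophageal reflux disorder,other,Sweden,both,2178,95,370
Irritable bowel syndrome,other,Norway,both,1252,14,97
Coronary heart disease death,cardiovascular,Sweden,both,3644,250,875
Stroke-related death,cardiovascular,Denmark,both,3852,35,316
General dystocia (female),genitourinary,Sweden,female,928,40,173
Pelvic organ prolapse (female),genitourinary,Sweden,female,3376,34,157
Stress urinary incontinence (female),genitourinary,Sweden,female,3376,13,87
Migraine,neurological,European Union,both,9077,382,1377
Rheumatoid arthritis,autoimmune,Finland,both,4137,9,64
Asthma,lung,Denmark,both,5084,257,447
Parkinson disease,neurological,Sweden,both,8590,9,151
Chronic obstructive pulmonary disease,lung,"Sweden, Denmark",both,7747,18,149
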