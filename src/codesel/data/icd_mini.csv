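code,parent,label
Chapter IX,,Diseases of the circulatory system
I10-I15,Chapter IX,Hypertensive diseases
I10,I10-I15,Essential (primary) hypertension
I20-I25,Chapter IX,Ischaemic heart diseases
I20,I20-I25,Angina pectoris
I200,I20,Unstable angina
I21,I20-I25,Acute myocardial infarction
I214,I21,Acute subendocardial myocardial infarction
I25,I20-I25,Chronic ischaemic heart disease
I251,I25,Atherosclerotic heart disease
I255,I25,Ischaemic cardiomyopathy
I259,I25,"Chronic ischaemic heart disease, unspecified"
I50,I30-I52,Heart failure
I30-I52,Chapter IX,Other forms of heart disease
I500,I50,Congestive heart failure
Chapter X,,Diseases of the respiratory system
J40-J47,Chapter X,Chronic lower respiratory diseases
J44,J40-J47,Other chronic obstructive pulmonary disease
J441,J44,COPD with acute exacerbation
Chapter IV,,"Endocrine, nutritional and metabolic diseases"
E10-E14,Chapter IV,Diabetes mellitus
E11,E10-E14,Type 2 diabetes mellitus
E112,E11,Type 2 diabetes with renal complications
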