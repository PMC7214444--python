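concept_id,domain,label
G_MALE,demographic,Male
G_FEMALE,demographic,Female
G_UNKNOWN,demographic,Gender unknown
R_WHITE,demographic,White
R_BLACK,demographic,Black or African American
R_ASIAN,demographic,Asian
R_HISPANIC,demographic,Hispanic or Latino
R_MULTIRACIAL,demographic,Multi-racial
R_NATIVE_AM,demographic,Native American or Alaska Native
R_PACIFIC,demographic,Native Hawaiian or Pacific Islander
R_OTHER,demographic,Other race
R_UNKNOWN,demographic,Race unknown
E_UNKNOWN,demographic,Ethnicity unknown
C_DM,condition,Diabetes mellitus
C_T1DM,condition,Type 1 diabetes mellitus
C_T2DM,condition,Type 2 diabetes mellitus
C_DM_NEPHRO,condition,Diabetic nephropathy
C_RETINOPATHY,condition,Diabetic retinopathy
C_NEUROPATHY,condition,Diabetic neuropathy
C_HTN,condition,Hypertensive disorder
C_ESS_HTN,condition,Essential hypertension
C_ACS,condition,Acute coronary syndrome
C_UA,condition,Unstable angina
C_NSTEMI,condition,Myocardial infarction without ST elevation
C_STEMI,condition,Myocardial infarction with ST elevation
C_MI,condition,Myocardial infarction
C_MI_HISTORY,condition,History of myocardial infarction
C_ANGINA,condition,Angina pectoris
C_UA_HOSP,condition,Hospitalization for unstable angina
C_STROKE,condition,Cerebrovascular accident
C_PAD,condition,Peripheral artery disease
C_LIPID_DISORDER,condition,Disorder of lipid metabolism
C_HYPERCHOL,condition,Hypercholesterolemia
C_RENAL_DISEASE,condition,Renal disease
C_CKD,condition,Chronic kidney disease
C_EGFR_LT60,condition,Documented eGFR below 60
C_LVH,condition,Left ventricular hypertrophy
C_AFIB,condition,Atrial fibrillation
C_SMOKING,condition,Current tobacco smoker
P_REVASC,procedure,Coronary revascularization
P_PCI,procedure,Percutaneous coronary intervention
P_CABG,procedure,Coronary artery bypass grafting
P_AMPUTATION,procedure,Amputation of lower limb
D_LIPID_LOWERING,drug,Lipid lowering agent
D_STATIN,drug,HMG-CoA reductase inhibitor
D_ATORVA,drug,Atorvastatin
D_PRAVA,drug,Pravastatin
D_FIBRATE,drug,Fibrate
D_AHT,drug,Antihypertensive agent
D_ACE,drug,ACE inhibitor
D_ARB,drug,Angiotensin receptor blocker
D_BB,drug,Beta blocker
D_CCB,drug,Calcium channel blocker
D_DIURETIC,drug,Thiazide diuretic
D_ANTIPLATELET,drug,Antiplatelet agent
D_ASPIRIN,drug,Aspirin
D_CLOPIDOGREL,drug,Clopidogrel
M_HBA1C,measurement,Hemoglobin A1c
M_FPG,measurement,Fasting plasma glucose
M_GLUCOSE,measurement,Serum glucose
M_BMI,measurement,Body mass index
M_WEIGHT,measurement,Body weight
M_SBP,measurement,Systolic blood pressure
M_DBP,measurement,Diastolic blood pressure
M_MAP,measurement,Mean arterial pressure
M_PULSE,measurement,Pulse rate
M_CREATININE,measurement,Serum creatinine
M_POTASSIUM,measurement,Serum potassium
M_TC,measurement,Total cholesterol
M_LDL,measurement,LDL cholesterol
M_HDL,measurement,HDL cholesterol
M_TG,measurement,Triglycerides
M_HGB,measurement,Hemoglobin
M_EGFR,measurement,Estimated glomerular filtration rate
M_UACR,measurement,Urinary albumin to creatinine ratio
M_WAIST,measurement,Waist circumference
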