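parent_id,child_id
C_DM,C_T1DM
C_DM,C_T2DM
C_DM,C_DM_NEPHRO
C_DM,C_RETINOPATHY
C_DM,C_NEUROPATHY
C_CKD,C_DM_NEPHRO
C_RENAL_DISEASE,C_CKD
C_HTN,C_ESS_HTN
C_ACS,C_UA
C_ACS,C_NSTEMI
C_ACS,C_STEMI
C_MI,C_NSTEMI
C_MI,C_STEMI
C_ANGINA,C_UA
C_LIPID_DISORDER,C_HYPERCHOL
P_REVASC,P_PCI
P_REVASC,P_CABG
D_LIPID_LOWERING,D_STATIN
D_LIPID_LOWERING,D_FIBRATE
D_STATIN,D_ATORVA
D_STATIN,D_PRAVA
D_AHT,D_ACE
D_AHT,D_ARB
D_AHT,D_BB
D_AHT,D_CCB
D_AHT,D_DIURETIC
D_ANTIPLATELET,D_ASPIRIN
D_ANTIPLATELET,D_CLOPIDOGREL
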