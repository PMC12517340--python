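drug,pt_term,ror,ci_low,ci_high
polatuzumab vedotin,CMV infection reactivation,181.41,145.86,225.64
polatuzumab vedotin,DLBCL,181.16,157.95,207.79
polatuzumab vedotin,Lymphoma,77.90,68.68,88.37
polatuzumab vedotin,CMV test positive,63.51,44.48,90.68
polatuzumab vedotin,Disease progression,61.69,57.64,66.03
polatuzumab vedotin,Blood lactate dehydrogenase,57.05,50.15,64.89
polatuzumab vedotin,Hypogammaglobulinemia,43.96,32.82,58.87
polatuzumab vedotin,CMV infection,27.86,22.84,33.99
polatuzumab vedotin,TLS,25.00,18.56,33.67
polatuzumab vedotin,Neutrophil count decreased,24.46,21.16,28.28
polatuzumab vedotin,Lymphocyte count decreased,23.96,19.44,29.54
polatuzumab vedotin,Myelosuppression,21.84,17.75,26.86
polatuzumab vedotin,FN,17.53,15.32,20.05
polatuzumab vedotin,Neutropenia,10.58,9.39,11.91
polatuzumab vedotin,Pancytopenia,10.31,8.64,12.31
polatuzumab vedotin,Cytopenia,10.31,8.64,12.31
polatuzumab vedotin,COVID-19,9.32,8.25,10.52
polatuzumab vedotin,Platelet count decreased,9.11,7.92,10.47
polatuzumab vedotin,Thrombocytopenia,8.90,7.78,10.17
polatuzumab vedotin,C-reactive protein increased,7.97,6.23,10.21
polatuzumab vedotin,White blood cell count decreased,6.73,5.74,7.90
polatuzumab vedotin,Aspartate aminotransferase increased,6.71,5.45,8.26
polatuzumab vedotin,PN,6.32,5.27,7.58
polatuzumab vedotin,Anemia,5.98,5.27,6.79
polatuzumab vedotin,Leukopenia,5.84,4.55,7.49
polatuzumab vedotin,Hepatic function abnormal,4.78,3.53,6.48
polatuzumab vedotin,Therapeutic response decreased,3.25,2.38,4.44
brentuximab vedotin,Anaplastic large-cell lymphoma,1427.40,1100.08,1852.10
brentuximab vedotin,Hodgkin's disease,410.80,372.69,452.81
brentuximab vedotin,Peripheral sensory neuropathy,49.36,40.59,60.02
brentuximab vedotin,Pneumocystis jirovecii pneumonia,28.04,23.50,33.44
brentuximab vedotin,Polyneuropathy,27.07,22.57,32.48
brentuximab vedotin,FN,23.46,21.46,25.65
brentuximab vedotin,PN,16.86,15.45,18.40
brentuximab vedotin,Neutrophil count decreased,9.90,8.38,11.69
brentuximab vedotin,Neutropenia,9.48,8.63,10.41
brentuximab vedotin,Pancytopenia,7.66,6.58,8.93
brentuximab vedotin,Septic shock,7.66,6.40,9.18
brentuximab vedotin,Disease progression,7.36,6.56,8.25
brentuximab vedotin,Thrombocytopenia,6.71,5.99,7.53
brentuximab vedotin,Leukopenia,5.89,4.89,7.09
brentuximab vedotin,Sepsis,5.59,4.93,6.34
brentuximab vedotin,Infusion-related reaction,4.89,4.04,5.91
brentuximab vedotin,General physical health deterioration,4.84,4.19,5.59
brentuximab vedotin,Malignant neoplasm progression,4.59,3.93,5.35
brentuximab vedotin,White blood cell count decreased,4.41,3.81,5.11
brentuximab vedotin,Respiratory failure,4.39,3.68,5.23
brentuximab vedotin,Pyrexia,4.29,3.94,4.66
brentuximab vedotin,Off-label use,4.01,3.75,4.29
brentuximab vedotin,Anemia,3.77,3.35,4.24
brentuximab vedotin,Pleural effusion,3.57,2.90,4.39
brentuximab vedotin,Platelet count decreased,3.16,2.66,3.76
brentuximab vedotin,Tachycardia,2.73,2.26,3.31
brentuximab vedotin,Infection,2.68,2.27,3.17
brentuximab vedotin,Weight decreased,2.46,2.18,2.79
brentuximab vedotin,Hemoglobin decreased,2.44,2.02,2.96
brentuximab vedotin,Hypotension,2.29,1.98,2.65
brentuximab vedotin,Dehydration,2.26,1.89,2.70
brentuximab vedotin,Pneumonia,2.25,2.00,2.53
brentuximab vedotin,Chills,2.22,1.84,2.69
brentuximab vedotin,Abdominal pain,2.10,1.82,2.41
brentuximab vedotin,Decreased appetite,1.80,1.55,2.10
brentuximab vedotin,Death,1.61,1.47,1.76
enfortumab vedotin,Taste disorder,69.32,48.27,99.56
enfortumab vedotin,Skin toxicity,53.00,42.82,65.59
enfortumab vedotin,Hepatic function abnormal,48.30,41.72,55.92
enfortumab vedotin,Myelosuppression,42.93,34.21,53.86
enfortumab vedotin,TEN,29.81,22.24,39.95
enfortumab vedotin,PN,28.44,24.70,32.76
enfortumab vedotin,Hyperglycemia,24.22,19.71,29.77
enfortumab vedotin,Malignant neoplasm progression,21.97,18.85,25.60
enfortumab vedotin,SJS,20.89,15.81,27.59
enfortumab vedotin,Skin disorder,20.17,15.72,25.88
enfortumab vedotin,Drug eruption,19.16,13.43,27.33
enfortumab vedotin,Metastases to the liver,14.43,9.65,21.59
enfortumab vedotin,Neutrophil count decreased,10.71,7.77,14.76
enfortumab vedotin,Rash,7.59,6.69,8.61
enfortumab vedotin,Dry eye,7.35,5.03,10.75
enfortumab vedotin,Interstitial lung disease,7.12,4.99,10.15
enfortumab vedotin,FN,7.06,5.18,9.62
enfortumab vedotin,Decreased appetite,6.50,5.48,7.72
enfortumab vedotin,Neutropenia,6.21,4.95,7.80
enfortumab vedotin,Alopecia,5.96,4.93,7.22
enfortumab vedotin,Rash erythematous,5.41,3.64,8.02
enfortumab vedotin,Stomatitis,4.22,2.82,6.32
enfortumab vedotin,Skin exfoliation,4.14,2.89,5.94
enfortumab vedotin,Disease progression,3.66,2.65,5.04
enfortumab vedotin,Thrombocytopenia,3.29,2.39,4.54
enfortumab vedotin,Renal impairment,3.27,2.24,4.79
enfortumab vedotin,Anemia,3.22,2.50,4.16
enfortumab vedotin,Pruritus,3.04,2.49,3.70
enfortumab vedotin,Dehydration,3.02,2.21,4.11
enfortumab vedotin,Sepsis,2.81,1.98,3.99
enfortumab vedotin,Pyrexia,2.75,2.24,3.37
enfortumab vedotin,Acute kidney injury,2.74,2.08,3.61
enfortumab vedotin,Inappropriate schedule of product administration,2.58,1.95,3.40
enfortumab vedotin,Urinary tract infection,2.55,1.87,3.49
enfortumab vedotin,Diarrhea,2.49,2.10,2.95
enfortumab vedotin,Malaise,2.39,1.95,2.92
enfortumab vedotin,Hypoesthesia,2.33,1.67,3.25
enfortumab vedotin,Weight decreased,2.22,1.71,2.88
enfortumab vedotin,Fatigue,1.97,1.65,2.34
enfortumab vedotin,Erythema,1.66,1.18,2.35
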