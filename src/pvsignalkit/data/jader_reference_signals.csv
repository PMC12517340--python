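drug,pt_term,n,ror,ci_low,ci_high
polatuzumab vedotin,CMV infection reactivation,29,30.15,20.79,43.72
polatuzumab vedotin,Lymphocyte count decreased,116,28.79,23.82,34.79
polatuzumab vedotin,Cytopenia,38,19.94,14.42,27.56
polatuzumab vedotin,CMV enterocolitis,24,17.04,11.36,25.56
polatuzumab vedotin,CMV infection,87,14.30,11.52,17.75
polatuzumab vedotin,CRS,13,13.23,7.64,22.90
polatuzumab vedotin,Neutrophil count decreased,348,13.22,11.78,14.83
polatuzumab vedotin,CMV viremia,27,12.66,8.64,18.54
polatuzumab vedotin,TLS,30,12.10,8.42,17.39
polatuzumab vedotin,Pneumonia cytomegaloviral,10,10.83,5.80,20.22
polatuzumab vedotin,White blood cell count decreased,157,6.23,5.30,7.33
polatuzumab vedotin,Platelet count decreased,203,6.18,5.35,7.15
polatuzumab vedotin,COVID-19,15,6.13,3.68,10.20
polatuzumab vedotin,Bacteremia,10,5.80,3.11,10.81
polatuzumab vedotin,Anemia,113,4.87,4.03,5.89
polatuzumab vedotin,FN,106,4.73,3.89,5.76
polatuzumab vedotin,Myelosuppression,51,4.18,3.16,5.51
polatuzumab vedotin,Neutropenia,75,3.26,2.59,4.10
polatuzumab vedotin,Infection,11,2.63,1.45,4.76
polatuzumab vedotin,PN,16,2.28,1.39,3.73
polatuzumab vedotin,Thrombocytopenia,25,1.90,1.28,2.82
polatuzumab vedotin,Sepsis,21,1.85,1.20,2.84
polatuzumab vedotin,Pneumocystis jirovecii pneumonia,15,1.85,1.11,3.07
polatuzumab vedotin,Decreased appetite,25,1.54,1.04,2.29
polatuzumab vedotin,Pneumonia,41,1.46,1.07,1.98
brentuximab vedotin,Anaplastic large-cell lymphoma,47,1356.19,852.38,2157.79
brentuximab vedotin,Hodgkin's disease recurrent,20,974.46,509.89,1862.31
brentuximab vedotin,Peripheral T-cell lymphoma unspecified,30,134.81,91.49,198.65
brentuximab vedotin,Hodgkin's disease,90,130.63,104.28,163.62
brentuximab vedotin,PN,403,57.62,51.69,64.23
brentuximab vedotin,Adult T-cell lymphoma/leukemia,12,46.30,25.85,82.92
brentuximab vedotin,Disease progression,138,37.98,31.89,45.24
brentuximab vedotin,Peripheral sensory neuropathy,10,17.82,9.51,33.38
brentuximab vedotin,Condition aggravated,52,9.82,7.45,12.95
brentuximab vedotin,Neutropenia,194,7.15,6.17,8.27
brentuximab vedotin,FN,188,6.99,6.02,8.11
brentuximab vedotin,Neutrophil count decreased,202,5.62,4.87,6.49
brentuximab vedotin,Ileus paralytic,11,4.63,2.56,8.38
brentuximab vedotin,TLS,10,3.21,1.72,5.99
brentuximab vedotin,Myelosuppression,47,3.10,2.32,4.14
brentuximab vedotin,Pneumocystis jirovecii pneumonia,28,2.81,1.93,4.08
brentuximab vedotin,Pancreatitis acute,10,2.16,1.16,4.02
brentuximab vedotin,Sepsis,29,2.07,1.44,2.99
brentuximab vedotin,Pneumonia,67,1.94,1.53,2.48
enfortumab vedotin,PN,264,58.98,51.61,67.40
enfortumab vedotin,Dermatitis bullous,12,46.84,26.28,83.48
enfortumab vedotin,Skin disorder,23,25.44,16.79,38.54
enfortumab vedotin,Metastases to the liver,15,22.42,13.43,37.43
enfortumab vedotin,Malignant neoplasm progression,77,15.32,12.17,19.28
enfortumab vedotin,Pulmonary toxicity,10,12.57,6.73,23.47
enfortumab vedotin,Pyelonephritis,16,11.06,6.75,18.14
enfortumab vedotin,Hyperglycemia,30,10.91,7.59,15.68
enfortumab vedotin,Myelosuppression,68,7.29,5.71,9.29
enfortumab vedotin,COVID-19,11,5.76,3.18,10.44
enfortumab vedotin,TEN,23,3.51,2.32,5.30
enfortumab vedotin,Decreased appetite,42,3.38,2.48,4.59
enfortumab vedotin,Pruritus,11,2.88,1.59,5.21
enfortumab vedotin,SJS,23,2.35,1.56,3.55
enfortumab vedotin,Interstitial lung disease,96,2.19,1.78,2.70
enfortumab vedotin,Drug eruption,27,2.07,1.41,3.03
enfortumab vedotin,Erythema,14,2.05,1.21,3.46
enfortumab vedotin,Rash,32,2.02,1.42,2.86
enfortumab vedotin,FN,36,2.00,1.44,2.79
enfortumab vedotin,Anemia,37,1.98,1.43,2.74
enfortumab vedotin,Erythema multiforme,17,1.90,1.18,3.07
enfortumab vedotin,Diarrhea,28,1.86,1.28,2.70
enfortumab vedotin,Renal impairment,32,1.77,1.25,2.51
enfortumab vedotin,Pneumonia,36,1.65,1.18,2.29
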