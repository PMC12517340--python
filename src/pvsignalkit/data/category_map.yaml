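# Default preferred-term -> adverse-event-category map used when rolling up
# stratified signals.  Categories: hematological, infection, tumor_related,
# neurological, skin_related, other.  Unlisted terms default to "other".
# Matching is case-insensitive; edit or replace this file to override.

# hematological
Lymphocyte count decreased: hematological
Cytopenia: hematological
Neutrophil count decreased: hematological
White blood cell count decreased: hematological
Platelet count decreased: hematological
Anemia: hematological
Anaemia: hematological
FN: hematological
Febrile neutropenia: hematological
Myelosuppression: hematological
Neutropenia: hematological
Thrombocytopenia: hematological
Pancytopenia: hematological
Leukopenia: hematological
Hemoglobin decreased: hematological

# infection
CMV infection reactivation: infection
CMV enterocolitis: infection
CMV infection: infection
CMV viremia: infection
CMV test positive: infection
Pneumonia cytomegaloviral: infection
COVID-19: infection
Bacteremia: infection
Infection: infection
Sepsis: infection
Septic shock: infection
Pneumocystis jirovecii pneumonia: infection
Pneumonia: infection
Pyelonephritis: infection
Urinary tract infection: infection

# tumor-related
TLS: tumor_related
Tumour lysis syndrome: tumor_related
Anaplastic large-cell lymphoma: tumor_related
Hodgkin's disease recurrent: tumor_related
Hodgkin's disease: tumor_related
Peripheral T-cell lymphoma unspecified: tumor_related
Adult T-cell lymphoma/leukemia: tumor_related
Disease progression: tumor_related
Condition aggravated: tumor_related
Malignant neoplasm progression: tumor_related
Metastases to the liver: tumor_related
DLBCL: tumor_related
Lymphoma: tumor_related

# neurological
PN: neurological
Peripheral neuropathy: neurological
Peripheral sensory neuropathy: neurological
Polyneuropathy: neurological
Hypoesthesia: neurological
Taste disorder: neurological

# skin-related
Dermatitis bullous: skin_related
Skin disorder: skin_related
Skin toxicity: skin_related
Skin exfoliation: skin_related
TEN: skin_related
SJS: skin_related
Drug eruption: skin_related
Erythema: skin_related
Erythema multiforme: skin_related
Rash: skin_related
Rash erythematous: skin_related
Pruritus: skin_related
Alopecia: skin_related

# other (explicit for documentation; anything unlisted is also "other")
CRS: other
Decreased appetite: other
Pancreatitis acute: other
Ileus paralytic: other
Hyperglycemia: other
Interstitial lung disease: other
Diarrhea: other
Renal impairment: other
Pulmonary toxicity: other
Pyrexia: other
Nausea: other
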