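# Per-category integer weights for the four comorbidity scoring schemes.
# Sources:
#   charlson_original      — Charlson ME, Pompei P, Ales KL, MacKenzie CR.
#                            J Chronic Dis 1987;40:373-83.
#   charlson_updated       — Quan H, Li B, Couris CM, et al. Am J Epidemiol
#                            2011;173:676-82.
#   elixhauser_vanwalraven — van Walraven C, Austin PC, Jennings A, et al.
#                            Med Care 2009;47:626-33.
#   elixhauser_ahrq        — Moore BJ, White S, Washington R, et al.
#                            Med Care 2017;55:698-705 (in-hospital mortality
#                            index, v2017). Cardiac arrhythmias is not part of
#                            that model and carries weight 0; the published
#                            combined hypertension weight (-1) is assigned to
#                            both hypertension categories (the hierarchy makes
#                            them mutually exclusive at scoring time).
# map_version: 2025.1
scheme	index	category	weight
charlson_original	charlson	myocardial_infarction	1
charlson_original	charlson	congestive_heart_failure	1
charlson_original	charlson	peripheral_vascular_disease	1
charlson_original	charlson	cerebrovascular_disease	1
charlson_original	charlson	dementia	1
charlson_original	charlson	chronic_pulmonary_disease	1
charlson_original	charlson	rheumatic_disease	1
charlson_original	charlson	peptic_ulcer_disease	1
charlson_original	charlson	mild_liver_disease	1
charlson_original	charlson	diabetes_without_complications	1
charlson_original	charlson	diabetes_with_complications	2
charlson_original	charlson	hemiplegia_paraplegia	2
charlson_original	charlson	renal_disease	2
charlson_original	charlson	any_malignancy	2
charlson_original	charlson	moderate_severe_liver_disease	3
charlson_original	charlson	metastatic_solid_tumor	6
charlson_original	charlson	aids_hiv	6
charlson_updated	charlson	myocardial_infarction	0
charlson_updated	charlson	congestive_heart_failure	2
charlson_updated	charlson	peripheral_vascular_disease	0
charlson_updated	charlson	cerebrovascular_disease	0
charlson_updated	charlson	dementia	2
charlson_updated	charlson	chronic_pulmonary_disease	1
charlson_updated	charlson	rheumatic_disease	1
charlson_updated	charlson	peptic_ulcer_disease	0
charlson_updated	charlson	mild_liver_disease	2
charlson_updated	charlson	diabetes_without_complications	0
charlson_updated	charlson	diabetes_with_complications	1
charlson_updated	charlson	hemiplegia_paraplegia	2
charlson_updated	charlson	renal_disease	1
charlson_updated	charlson	any_malignancy	2
charlson_updated	charlson	moderate_severe_liver_disease	4
charlson_updated	charlson	metastatic_solid_tumor	6
charlson_updated	charlson	aids_hiv	4
elixhauser_vanwalraven	elixhauser	congestive_heart_failure	7
elixhauser_vanwalraven	elixhauser	cardiac_arrhythmias	5
elixhauser_vanwalraven	elixhauser	valvular_disease	-1
elixhauser_vanwalraven	elixhauser	pulmonary_circulation_disorders	4
elixhauser_vanwalraven	elixhauser	peripheral_vascular_disorders	2
elixhauser_vanwalraven	elixhauser	hypertension_uncomplicated	0
elixhauser_vanwalraven	elixhauser	hypertension_complicated	0
elixhauser_vanwalraven	elixhauser	paralysis	7
elixhauser_vanwalraven	elixhauser	other_neurological_disorders	6
elixhauser_vanwalraven	elixhauser	chronic_pulmonary_disease	3
elixhauser_vanwalraven	elixhauser	diabetes_uncomplicated	0
elixhauser_vanwalraven	elixhauser	diabetes_complicated	0
elixhauser_vanwalraven	elixhauser	hypothyroidism	0
elixhauser_vanwalraven	elixhauser	renal_failure	5
elixhauser_vanwalraven	elixhauser	liver_disease	11
elixhauser_vanwalraven	elixhauser	peptic_ulcer_disease_excluding_bleeding	0
elixhauser_vanwalraven	elixhauser	aids_hiv	0
elixhauser_vanwalraven	elixhauser	lymphoma	9
elixhauser_vanwalraven	elixhauser	metastatic_cancer	12
elixhauser_vanwalraven	elixhauser	solid_tumour_without_metastasis	4
elixhauser_vanwalraven	elixhauser	rheumatoid_arthritis_collagen_vascular	0
elixhauser_vanwalraven	elixhauser	coagulopathy	3
elixhauser_vanwalraven	elixhauser	obesity	-4
elixhauser_vanwalraven	elixhauser	weight_loss	6
elixhauser_vanwalraven	elixhauser	fluid_electrolyte_disorders	5
elixhauser_vanwalraven	elixhauser	blood_loss_anaemia	-2
elixhauser_vanwalraven	elixhauser	deficiency_anaemia	-2
elixhauser_vanwalraven	elixhauser	alcohol_abuse	0
elixhauser_vanwalraven	elixhauser	drug_abuse	-7
elixhauser_vanwalraven	elixhauser	psychoses	0
elixhauser_vanwalraven	elixhauser	depression	-3
elixhauser_ahrq	elixhauser	congestive_heart_failure	9
elixhauser_ahrq	elixhauser	cardiac_arrhythmias	0
elixhauser_ahrq	elixhauser	valvular_disease	0
elixhauser_ahrq	elixhauser	pulmonary_circulation_disorders	6
elixhauser_ahrq	elixhauser	peripheral_vascular_disorders	3
elixhauser_ahrq	elixhauser	hypertension_uncomplicated	-1
elixhauser_ahrq	elixhauser	hypertension_complicated	-1
elixhauser_ahrq	elixhauser	paralysis	4
elixhauser_ahrq	elixhauser	other_neurological_disorders	5
elixhauser_ahrq	elixhauser	chronic_pulmonary_disease	3
elixhauser_ahrq	elixhauser	diabetes_uncomplicated	0
elixhauser_ahrq	elixhauser	diabetes_complicated	-1
elixhauser_ahrq	elixhauser	hypothyroidism	0
elixhauser_ahrq	elixhauser	renal_failure	6
elixhauser_ahrq	elixhauser	liver_disease	4
elixhauser_ahrq	elixhauser	peptic_ulcer_disease_excluding_bleeding	0
elixhauser_ahrq	elixhauser	aids_hiv	0
elixhauser_ahrq	elixhauser	lymphoma	6
elixhauser_ahrq	elixhauser	metastatic_cancer	14
elixhauser_ahrq	elixhauser	solid_tumour_without_metastasis	7
elixhauser_ahrq	elixhauser	rheumatoid_arthritis_collagen_vascular	0
elixhauser_ahrq	elixhauser	coagulopathy	11
elixhauser_ahrq	elixhauser	obesity	-5
elixhauser_ahrq	elixhauser	weight_loss	9
elixhauser_ahrq	elixhauser	fluid_electrolyte_disorders	11
elixhauser_ahrq	elixhauser	blood_loss_anaemia	-3
elixhauser_ahrq	elixhauser	deficiency_anaemia	-2
elixhauser_ahrq	elixhauser	alcohol_abuse	-1
elixhauser_ahrq	elixhauser	drug_abuse	-7
elixhauser_ahrq	elixhauser	psychoses	-6
elixhauser_ahrq	elixhauser	depression	-5
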