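# Comorbidity hierarchy: the mild category is suppressed (set to 0) at scoring
# time when its severe partner is present, preventing double counting.
# map_version: 2025.1
index	mild	severe
charlson	mild_liver_disease	moderate_severe_liver_disease
charlson	diabetes_without_complications	diabetes_with_complications
charlson	any_malignancy	metastatic_solid_tumor
elixhauser	hypertension_uncomplicated	hypertension_complicated
elixhauser	diabetes_uncomplicated	diabetes_complicated
elixhauser	solid_tumour_without_metastasis	metastatic_cancer
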