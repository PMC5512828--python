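# Example mapping from source-EMR condition strings to the package's
# controlled vocabulary; pass to read_cohort(condition_map=...) or adapt.
Atrial fibrillation: other_cvd
AF: other_cvd
MI: myocardial_infarction
IHD: stable_angina
Stroke: cv_or_cerebrovascular_complication
TIA: cv_or_cerebrovascular_complication
CHF: congestive_heart_failure
PVD: peripheral_vascular_disease
PCI: angioplasty
HTN: hypertension
DM: diabetes
COPD: copd
Asthma: asthma
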