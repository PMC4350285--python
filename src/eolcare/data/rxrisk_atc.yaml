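# Medication-based comorbidity categories (RxRisk-style) as ATC prefix
# lists.  Condensed adaptation of a published ATC mapping: a category is
# ascertained when any dispensing in the look-back window matches one of
# its prefixes; each category counts once.  Replace with a full published
# mapping file for production use.
anticoagulation: [B01AA, B01AB, B01AE, B01AF, B01AX]
antiplatelet: [B01AC]
pain: [N02A]
pain_inflammation: [M01A]
anxiety: [N05B]
depression: [N06A]
psychosis: [N05A]
bipolar: [N05AN]
epilepsy: [N03]
parkinsons: [N04]
dementia: [N06D]
diabetes: [A10]
thyroid: [H03]
gout: [M04]
osteoporosis: [M05B]
hyperlipidaemia: [C10]
hypertension: [C03, C09]
cardiac_disease: [C01, C07, C08]
airways_disease: [R03]
gastric_acid: [A02B]
glaucoma: [S01E]
malignancy: [L01, L02]
transplant_immunology: [L04]
benign_prostatic_hyperplasia: [G04C]
incontinence: [G04BD]
smoking_cessation: [N07BA]
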