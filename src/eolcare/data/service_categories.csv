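# Synthetic service-item catalogue with category assignments. Real MBS/DVA
# item numbers and the expert categorisation of them are not reproduced;
# these invented item_ids are the catalogue the simulator draws from and the
# default mapping the classifier loads. admin_billing items are excluded
# from resource-use counts but retained in cost analyses.
item_id,category
PATH01,diagnostics_imaging_pathology
PATH02,diagnostics_imaging_pathology
IMG01,diagnostics_imaging_pathology
GP01,practitioner_visit
GP02,practitioner_visit
SPEC01,practitioner_visit
PALL01,practitioner_visit
ALLIED01,allied_health_nursing_careplan
NURSE01,allied_health_nursing_careplan
CAREPLAN01,allied_health_nursing_careplan
MDC01,allied_health_nursing_careplan
CHEMO01,therapeutic_procedure
RADONC01,therapeutic_procedure
PROC01,therapeutic_procedure
SURG01,surgery
SURG02,surgery
DENT01,dental
DENT02,dental
BULK01,admin_billing
BULK02,admin_billing
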