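category,prefixes,weight,supersedes
myocardial_infarction,410;412,1,
congestive_heart_failure,428,1,
peripheral_vascular_disease,4439;441;7854;V434,1,
cerebrovascular_disease,430;431;432;433;434;435;436;437;438,1,
dementia,290,1,
chronic_pulmonary_disease,490;491;492;493;494;495;496;500;501;502;503;504;505;5064,1,
rheumatologic_disease,7100;7101;7104;7140;7141;7142;71481;5171;725,1,
peptic_ulcer_disease,531;532;533;534,1,
mild_liver_disease,5712;5714;5715;5716,1,
diabetes,2500;2501;2502;2503;2507,1,
diabetes_with_complications,2504;2505;2506,2,diabetes
hemiplegia_paraplegia,342;3441,2,
renal_disease,582;5830;5831;5832;5834;5836;5837;585;586;5880,2,
malignancy,14;15;16;170;171;172;174;175;176;179;18;190;191;192;193;194;195;200;201;202;203;204;205;206;207;208,2,
moderate_severe_liver_disease,4560;4561;4562;5722;5723;5724;5728,3,mild_liver_disease
metastatic_solid_tumor,196;197;198;1990;1991,6,malignancy
aids,042;043;044,6,
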