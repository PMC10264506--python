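name,family,mean,ci_low,ci_high,group,units,source
age,normal,64.1,46.9,80.7,,years,EC survivor cohort
p_cvd_baseline,beta,0.158,0.144,0.172,,probability,EC survivor cohort (14-year follow-up)
share_stroke,dirichlet,0.35,,,cvd_split,proportion,EC survivor cohort
share_chd,dirichlet,0.31,,,cvd_split,proportion,EC survivor cohort
share_hf,dirichlet,0.34,,,cvd_split,proportion,EC survivor cohort
p_fatal_stroke,lognormal,0.478,0.360,0.586,,probability,uterine cancer SMR study
p_fatal_chd_hf,lognormal,0.424,0.342,0.493,,probability,uterine cancer SMR study
surv5_post_chd,beta,0.859,0.832,0.885,,probability,Australian longitudinal study
surv5_post_stroke,beta,0.731,0.628,0.824,,probability,Australian longitudinal study
surv5_post_hf,beta,0.705,0.703,0.707,,probability,Australian longitudinal study
p_recurrence,beta,0.240,0.205,0.278,,probability,EC survivor cohort (14-year follow-up)
age_specific_mortality,table,,,,,probability,ABS Australian Life Table 2022 (external age-indexed input)
surv5_post_recurrence,beta,0.625,0.462,0.775,,probability,SEER regional-stage relative survival
hr_cvd_exercise,lognormal,0.770,0.67,0.88,,hazard ratio,breast cancer survivor exercise study
hr_recurrence_exercise,lognormal,0.330,0.17,0.64,,hazard ratio,EC case-control study
u_baseline,table,,,,,utility,EQ-5D-3L Australian EC survivor norms (external age-indexed input)
du_recurrence,gamma,0.112,0.09985,0.1246,,disutility,utility study
u_post_stroke,beta,0.651,0.474,0.810,,utility,general-population utility review
u_post_chd,beta,0.720,0.650,0.787,,utility,systematic review (375 studies)
u_post_hf,beta,0.789,0.727,0.846,,utility,systematic review (375 studies)
du_stroke_event,gamma,0.075,0.0423,0.116,,disutility,utility study
du_chd_event,gamma,0.15,0.0843,0.230,,disutility,utility study
du_hf_event,gamma,0.07,0.0398,0.108,,disutility,utility study
c_exercise,gamma,1381,377,3006,,AUD,ACUMEN trial (18 AEP-supervised sessions)
c_surveillance,gamma,1601,40,5930,,AUD,MBS
c_stroke_treatment,gamma,12215,3293,26650,,AUD,Australian costing study
c_chd_treatment,gamma,10177,2847,22383,,AUD,Australian costing study
c_hf_treatment,gamma,10270,2830,22577,,AUD,Australian costing study
c_post_stroke_fu,gamma,5662,1502,12353,,AUD,Australian costing study
c_post_chd_fu,gamma,3348,951,7360,,AUD,Australian costing study
c_post_hf_fu,gamma,4101,1086,9047,,AUD,Australian costing study
c_recurrence_treatment,gamma,13126,3558,28773,,AUD,MBS (EBRT + VBT)
c_post_cancer_fu,gamma,4880,1348,10642,,AUD,Australian costing study
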