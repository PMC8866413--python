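# Pooled Cohort Equations: 10-year first atherosclerotic cardiovascular
# disease event, sex- and race-group-specific proportional-hazards
# coefficients over transformed predictors.
# Citation: Goff DC Jr, Lloyd-Jones DM, Bennett G, et al. 2013 ACC/AHA
# Guideline on the Assessment of Cardiovascular Risk. Circulation
# 2014;129(25 Suppl 2):S49-S73 (Appendix 7, Table A).
# Units: total and HDL cholesterol in mg/dL, systolic blood pressure in
# mmHg, age in years. baseline_survival is S0(10); mean_term is the sum of
# coefficient x mean products reported alongside the published equations.
group,sex,term,value
white,female,ln_age,-29.799
white,female,ln_age_sq,4.884
white,female,ln_tc,13.540
white,female,ln_age_ln_tc,-3.114
white,female,ln_hdl,-13.578
white,female,ln_age_ln_hdl,3.149
white,female,ln_sbp_treated,2.019
white,female,ln_sbp_untreated,1.957
white,female,smoker,7.574
white,female,ln_age_smoker,-1.665
white,female,diabetes,0.661
white,female,baseline_survival,0.9665
white,female,mean_term,-29.18
white,male,ln_age,12.344
white,male,ln_tc,11.853
white,male,ln_age_ln_tc,-2.664
white,male,ln_hdl,-7.990
white,male,ln_age_ln_hdl,1.769
white,male,ln_sbp_treated,1.797
white,male,ln_sbp_untreated,1.764
white,male,smoker,7.837
white,male,ln_age_smoker,-1.795
white,male,diabetes,0.658
white,male,baseline_survival,0.9144
white,male,mean_term,61.18
black,female,ln_age,17.114
black,female,ln_tc,0.940
black,female,ln_hdl,-18.920
black,female,ln_age_ln_hdl,4.475
black,female,ln_sbp_treated,29.291
black,female,ln_age_ln_sbp_treated,-6.432
black,female,ln_sbp_untreated,27.820
black,female,ln_age_ln_sbp_untreated,-6.087
black,female,smoker,0.691
black,female,diabetes,0.874
black,female,baseline_survival,0.9533
black,female,mean_term,86.61
black,male,ln_age,2.469
black,male,ln_tc,0.302
black,male,ln_hdl,-0.307
black,male,ln_sbp_treated,1.916
black,male,ln_sbp_untreated,1.809
black,male,smoker,0.549
black,male,diabetes,0.645
black,male,baseline_survival,0.8954
black,male,mean_term,19.54
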