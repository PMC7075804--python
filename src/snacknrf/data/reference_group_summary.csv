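contrast,group,n,variable,mean,sem
first_ingredient,fruit_or_dairy,115,pct_dv_protein,6.13,0.46
first_ingredient,fruit_or_dairy,115,pct_dv_fiber,3.63,0.58
first_ingredient,fruit_or_dairy,115,pct_dv_vitamin_a,5.48,0.80
first_ingredient,fruit_or_dairy,115,pct_dv_vitamin_c,12.14,2.30
first_ingredient,fruit_or_dairy,115,pct_dv_vitamin_d,3.03,0.48
first_ingredient,fruit_or_dairy,115,pct_dv_calcium,10.40,1.08
first_ingredient,fruit_or_dairy,115,pct_dv_iron,1.47,0.33
first_ingredient,fruit_or_dairy,115,pct_dv_potassium,3.35,0.22
first_ingredient,fruit_or_dairy,115,pct_mrv_saturated_fat,5.29,0.64
first_ingredient,fruit_or_dairy,115,pct_mrv_total_sugar,16.28,0.76
first_ingredient,fruit_or_dairy,115,pct_mrv_added_sugar,9.25,0.92
first_ingredient,fruit_or_dairy,115,pct_mrv_sodium,2.06,0.21
first_ingredient,fruit_or_dairy,115,energy_density,126,9
first_ingredient,fruit_or_dairy,115,nr_subscore,45.65,2.46
first_ingredient,fruit_or_dairy,115,lim_subscore,16.60,1.20
first_ingredient,fruit_or_dairy,115,nrf_score,29.05,3.01
first_ingredient,neither,146,pct_dv_protein,2.71,0.18
first_ingredient,neither,146,pct_dv_fiber,2.39,0.28
first_ingredient,neither,146,pct_dv_vitamin_a,1.15,0.43
first_ingredient,neither,146,pct_dv_vitamin_c,6.16,1.50
first_ingredient,neither,146,pct_dv_vitamin_d,0.31,0.11
first_ingredient,neither,146,pct_dv_calcium,2.44,0.35
first_ingredient,neither,146,pct_dv_iron,3.08,0.32
first_ingredient,neither,146,pct_dv_potassium,0.99,0.10
first_ingredient,neither,146,pct_mrv_saturated_fat,6.00,0.47
first_ingredient,neither,146,pct_mrv_total_sugar,10.62,0.65
first_ingredient,neither,146,pct_mrv_added_sugar,11.66,1.10
first_ingredient,neither,146,pct_mrv_sodium,2.53,0.18
first_ingredient,neither,146,energy_density,395,12
first_ingredient,neither,146,nr_subscore,19.12,1.80
first_ingredient,neither,146,lim_subscore,20.19,1.11
first_ingredient,neither,146,nrf_score,-1.07,2.25
fvn,fvn,88,pct_dv_protein,4.03,0.43
fvn,fvn,88,pct_dv_fiber,5.04,0.60
fvn,fvn,88,pct_dv_vitamin_a,2.81,0.74
fvn,fvn,88,pct_dv_vitamin_c,15.98,2.90
fvn,fvn,88,pct_dv_vitamin_d,1.66,0.42
fvn,fvn,88,pct_dv_calcium,5.30,1.26
fvn,fvn,88,pct_dv_iron,2.16,0.44
fvn,fvn,88,pct_dv_potassium,2.96,0.26
fvn,fvn,88,pct_mrv_saturated_fat,3.42,0.47
fvn,fvn,88,pct_mrv_total_sugar,16.89,0.94
fvn,fvn,88,pct_mrv_added_sugar,8.34,1.06
fvn,fvn,88,pct_mrv_sodium,1.21,0.13
fvn,fvn,88,energy_density,213,20
fvn,fvn,88,nr_subscore,40.00,3.30
fvn,fvn,88,lim_subscore,12.97,1.35
fvn,fvn,88,nrf_score,26.99,3.93
fvn,no_fvn,173,pct_dv_protein,4.31,0.31
fvn,no_fvn,173,pct_dv_fiber,1.86,0.30
fvn,no_fvn,173,pct_dv_vitamin_a,3.17,0.56
fvn,no_fvn,173,pct_dv_vitamin_c,5.13,1.27
fvn,no_fvn,173,pct_dv_vitamin_d,1.35,0.26
fvn,no_fvn,173,pct_dv_calcium,6.27,0.57
fvn,no_fvn,173,pct_dv_iron,2.49,0.28
fvn,no_fvn,173,pct_dv_potassium,1.55,0.14
fvn,no_fvn,173,pct_mrv_saturated_fat,6.84,0.51
fvn,no_fvn,173,pct_mrv_total_sugar,11.19,0.58
fvn,no_fvn,173,pct_mrv_added_sugar,11.67,0.96
fvn,no_fvn,173,pct_mrv_sodium,2.89,0.19
fvn,no_fvn,173,energy_density,309,13
fvn,no_fvn,173,nr_subscore,26.16,1.82
fvn,no_fvn,173,lim_subscore,21.49,0.97
fvn,no_fvn,173,nrf_score,4.68,2.14
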