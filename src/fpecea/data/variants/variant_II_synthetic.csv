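parameter,age_lower,age_upper,sex,value,low,high,sd,dist
p_vert_fracture,75,79,women,0.004,,,,beta
p_vert_fracture,80,84,women,0.008,,,,beta
p_vert_fracture,85,89,women,0.013,,,,beta
p_vert_fracture,90,94,women,0.019,,,,beta
p_vert_fracture,95,,women,0.024,,,,beta
p_vert_fracture,75,79,men,0.002,,,,beta
p_vert_fracture,80,84,men,0.004,,,,beta
p_vert_fracture,85,89,men,0.006,,,,beta
p_vert_fracture,90,94,men,0.01,,,,beta
p_vert_fracture,95,,men,0.013,,,,beta
p_vert_refracture,75,79,women,0.008,,,,beta
p_vert_refracture,80,84,women,0.014,,,,beta
p_vert_refracture,85,89,women,0.02,,,,beta
p_vert_refracture,90,94,women,0.026,,,,beta
p_vert_refracture,95,,women,0.03,,,,beta
p_vert_refracture,75,79,men,0.004,,,,beta
p_vert_refracture,80,84,men,0.007,,,,beta
p_vert_refracture,85,89,men,0.01,,,,beta
p_vert_refracture,90,94,men,0.014,,,,beta
p_vert_refracture,95,,men,0.017,,,,beta
p_mort_vert_acute,75,79,women,0.014,,,,beta
p_mort_vert_acute,80,84,women,0.024,,,,beta
p_mort_vert_acute,85,89,women,0.044,,,,beta
p_mort_vert_acute,90,94,women,0.095,,,,beta
p_mort_vert_acute,95,,women,0.095,,,,beta
p_mort_vert_acute,75,79,men,0.027,,,,beta
p_mort_vert_acute,80,84,men,0.045,,,,beta
p_mort_vert_acute,85,89,men,0.071,,,,beta
p_mort_vert_acute,90,94,men,0.111,,,,beta
p_mort_vert_acute,95,,men,0.111,,,,beta
p_mort_vert_post,75,79,women,0.009,,,,beta
p_mort_vert_post,80,84,women,0.016,,,,beta
p_mort_vert_post,85,89,women,0.029,,,,beta
p_mort_vert_post,90,94,women,0.063,,,,beta
p_mort_vert_post,95,,women,0.063,,,,beta
p_mort_vert_post,75,79,men,0.018,,,,beta
p_mort_vert_post,80,84,men,0.03,,,,beta
p_mort_vert_post,85,89,men,0.047,,,,beta
p_mort_vert_post,90,94,men,0.074,,,,beta
p_mort_vert_post,95,,men,0.074,,,,beta
vert_treatment_cost,75,,all,5000,,,,gamma
ltc_vert_post,75,79,women,495,,,,gamma
ltc_vert_post,80,84,women,1132,,,,gamma
ltc_vert_post,85,89,women,1637,,,,gamma
ltc_vert_post,90,,women,2260,,,,gamma
ltc_vert_post,75,79,men,459,,,,gamma
ltc_vert_post,80,84,men,1000,,,,gamma
ltc_vert_post,85,89,men,1374,,,,gamma
ltc_vert_post,90,,men,1882,,,,gamma
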