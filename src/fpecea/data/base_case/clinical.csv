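parameter,age_lower,age_upper,sex,value,low,high,dist
p_first_fracture,75,79,women,0.003,,,beta
p_first_fracture,80,84,women,0.006,,,beta
p_first_fracture,85,89,women,0.01,,,beta
p_first_fracture,90,94,women,0.015,,,beta
p_first_fracture,95,,women,0.019,,,beta
p_first_fracture,75,79,men,0.002,,,beta
p_first_fracture,80,84,men,0.003,,,beta
p_first_fracture,85,89,men,0.005,,,beta
p_first_fracture,90,94,men,0.009,,,beta
p_first_fracture,95,,men,0.012,,,beta
p_first_fracture_late,75,79,women,0.004,,,beta
p_first_fracture_late,80,84,women,0.009,,,beta
p_first_fracture_late,85,89,women,0.014,,,beta
p_first_fracture_late,90,94,women,0.02,,,beta
p_first_fracture_late,95,,women,0.025,,,beta
p_first_fracture_late,75,79,men,0.002,,,beta
p_first_fracture_late,80,84,men,0.004,,,beta
p_first_fracture_late,85,89,men,0.007,,,beta
p_first_fracture_late,90,94,men,0.012,,,beta
p_first_fracture_late,95,,men,0.016,,,beta
p_refracture_acute,75,79,women,0.018,,,beta
p_refracture_acute,80,84,women,0.034,,,beta
p_refracture_acute,85,89,women,0.055,,,beta
p_refracture_acute,90,94,women,0.075,,,beta
p_refracture_acute,95,,women,0.094,,,beta
p_refracture_acute,75,79,men,0.009,,,beta
p_refracture_acute,80,84,men,0.017,,,beta
p_refracture_acute,85,89,men,0.027,,,beta
p_refracture_acute,90,94,men,0.043,,,beta
p_refracture_acute,95,,men,0.058,,,beta
p_refracture_late,75,79,women,0.019,,,beta
p_refracture_late,80,84,women,0.023,,,beta
p_refracture_late,85,89,women,0.027,,,beta
p_refracture_late,90,94,women,0.029,,,beta
p_refracture_late,95,,women,0.025,,,beta
p_refracture_late,75,79,men,0.013,,,beta
p_refracture_late,80,84,men,0.018,,,beta
p_refracture_late,85,89,men,0.021,,,beta
p_refracture_late,90,94,men,0.025,,,beta
p_refracture_late,95,,men,0.023,,,beta
p_refracture_nh,75,79,women,0.064,,,beta
p_refracture_nh,80,84,women,0.079,,,beta
p_refracture_nh,85,89,women,0.084,,,beta
p_refracture_nh,90,94,women,0.091,,,beta
p_refracture_nh,95,,women,0.069,,,beta
p_refracture_nh,75,79,men,0.03,,,beta
p_refracture_nh,80,84,men,0.043,,,beta
p_refracture_nh,85,89,men,0.039,,,beta
p_refracture_nh,90,94,men,0.047,,,beta
p_refracture_nh,95,,men,0.015,,,beta
p_nh_admission,75,79,women,0.067,,,beta
p_nh_admission,80,84,women,0.117,,,beta
p_nh_admission,85,89,women,0.147,,,beta
p_nh_admission,90,94,women,0.18,,,beta
p_nh_admission,95,,women,0.201,,,beta
p_nh_admission,75,79,men,0.066,,,beta
p_nh_admission,80,84,men,0.096,,,beta
p_nh_admission,85,89,men,0.106,,,beta
p_nh_admission,90,94,men,0.117,,,beta
p_nh_admission,95,,men,0.186,,,beta
p_mort_well,75,79,women,0.009,,,beta
p_mort_well,80,84,women,0.016,,,beta
p_mort_well,85,89,women,0.029,,,beta
p_mort_well,90,94,women,0.063,,,beta
p_mort_well,95,,women,0.063,,,beta
p_mort_well,75,79,men,0.018,,,beta
p_mort_well,80,84,men,0.03,,,beta
p_mort_well,85,89,men,0.047,,,beta
p_mort_well,90,94,men,0.074,,,beta
p_mort_well,95,,men,0.074,,,beta
p_mort_acute_fracture,75,79,women,0.038,,,beta
p_mort_acute_fracture,80,84,women,0.056,,,beta
p_mort_acute_fracture,85,89,women,0.073,,,beta
p_mort_acute_fracture,90,94,women,0.129,,,beta
p_mort_acute_fracture,95,,women,0.129,,,beta
p_mort_acute_fracture,75,79,men,0.082,,,beta
p_mort_acute_fracture,80,84,men,0.109,,,beta
p_mort_acute_fracture,85,89,men,0.13,,,beta
p_mort_acute_fracture,90,94,men,0.188,,,beta
p_mort_acute_fracture,95,,men,0.188,,,beta
p_mort_post_fracture,75,79,women,0.018,,,beta
p_mort_post_fracture,80,84,women,0.023,,,beta
p_mort_post_fracture,85,89,women,0.042,,,beta
p_mort_post_fracture,90,94,women,0.076,,,beta
p_mort_post_fracture,95,,women,0.076,,,beta
p_mort_post_fracture,75,79,men,0.032,,,beta
p_mort_post_fracture,80,84,men,0.045,,,beta
p_mort_post_fracture,85,89,men,0.069,,,beta
p_mort_post_fracture,90,94,men,0.101,,,beta
p_mort_post_fracture,95,,men,0.101,,,beta
p_mort_nh,75,79,women,0.134,,,beta
p_mort_nh,80,84,women,0.134,,,beta
p_mort_nh,85,89,women,0.161,,,beta
p_mort_nh,90,94,women,0.161,,,beta
p_mort_nh,95,,women,0.217,,,beta
p_mort_nh,75,79,men,0.224,,,beta
p_mort_nh,80,84,men,0.223,,,beta
p_mort_nh,85,89,men,0.266,,,beta
p_mort_nh,90,94,men,0.265,,,beta
p_mort_nh,95,,men,0.332,,,beta
p_mort_nh_refracture,75,79,women,0.252,,,beta
p_mort_nh_refracture,80,84,women,0.251,,,beta
p_mort_nh_refracture,85,89,women,0.298,,,beta
p_mort_nh_refracture,90,94,women,0.297,,,beta
p_mort_nh_refracture,95,,women,0.389,,,beta
p_mort_nh_refracture,75,79,men,0.435,,,beta
p_mort_nh_refracture,80,84,men,0.433,,,beta
p_mort_nh_refracture,85,89,men,0.501,,,beta
p_mort_nh_refracture,90,94,men,0.5,,,beta
p_mort_nh_refracture,95,,men,0.597,,,beta
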