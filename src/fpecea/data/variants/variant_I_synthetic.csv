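parameter,age_lower,age_upper,sex,value,low,high,dist
p_nh_other_well,75,79,women,0.004,,,beta
p_nh_other_well,80,84,women,0.008,,,beta
p_nh_other_well,85,89,women,0.017,,,beta
p_nh_other_well,90,94,women,0.035,,,beta
p_nh_other_well,95,,women,0.055,,,beta
p_nh_other_well,75,79,men,0.004,,,beta
p_nh_other_well,80,84,men,0.008,,,beta
p_nh_other_well,85,89,men,0.017,,,beta
p_nh_other_well,90,94,men,0.035,,,beta
p_nh_other_well,95,,men,0.055,,,beta
p_nh_other_post,75,79,women,0.004,,,beta
p_nh_other_post,80,84,women,0.008,,,beta
p_nh_other_post,85,89,women,0.017,,,beta
p_nh_other_post,90,94,women,0.035,,,beta
p_nh_other_post,95,,women,0.055,,,beta
p_nh_other_post,75,79,men,0.004,,,beta
p_nh_other_post,80,84,men,0.008,,,beta
p_nh_other_post,85,89,men,0.017,,,beta
p_nh_other_post,90,94,men,0.035,,,beta
p_nh_other_post,95,,men,0.055,,,beta
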