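parameter,age_lower,age_upper,sex,value,low,high,sd,dist
hospital_care,75,,all,7280,,,,gamma
revision,75,,all,961,,,,gamma
rehabilitation,75,,all,2209,,,,gamma
outpatient_care,75,,all,1114,,,,gamma
ltc_nursing_home,75,,all,8516,,,,gamma
ltc_well,75,79,women,394,,,,gamma
ltc_well,80,84,women,831,,,,gamma
ltc_well,85,89,women,1601,,,,gamma
ltc_well,90,,women,2550,,,,gamma
ltc_well,75,79,men,348,,,,gamma
ltc_well,80,84,men,651,,,,gamma
ltc_well,85,89,men,1221,,,,gamma
ltc_well,90,,men,2000,,,,gamma
ltc_post_fracture,75,79,women,990,,,,gamma
ltc_post_fracture,80,84,women,2264,,,,gamma
ltc_post_fracture,85,89,women,3274,,,,gamma
ltc_post_fracture,90,,women,4519,,,,gamma
ltc_post_fracture,75,79,men,918,,,,gamma
ltc_post_fracture,80,84,men,2000,,,,gamma
ltc_post_fracture,85,89,men,2748,,,,gamma
ltc_post_fracture,90,,men,3764,,,,gamma
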