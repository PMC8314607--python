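age,sex,count,remaining_life_expectancy_years
75,women,1200,13.0
80,women,950,9.5
85,women,600,6.5
90,women,250,4.2
75,men,900,11.0
80,men,600,8.0
85,men,300,5.5
90,men,90,3.6
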