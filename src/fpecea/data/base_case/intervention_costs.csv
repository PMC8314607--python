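program_year,sex,value,low,high,sd,dist
1,women,139,,,,gamma
2,women,93,,,,gamma
3,women,49,,,,gamma
4,women,5,,,,gamma
5,women,0,,,,gamma
1,men,139,,,,gamma
2,men,94,,,,gamma
3,men,49,,,,gamma
4,men,5,,,,gamma
5,men,0,,,,gamma
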