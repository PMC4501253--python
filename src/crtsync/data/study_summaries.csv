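name,mean_1,sd_1,n_1,mean_2,sd_2,n_2,group_1,group_2,source
max_wall_delay_pattern,371,117,13,471,106,20,type I,type II,"pattern associations table, row 'Maximum wall delay (ms)': 371 +/- 117 vs 471 +/- 106"
max_wall_delay_response,455,104,18,404,135,15,responders,non-responders,"cohort characteristics table, row 'Maximum wall delay (ms)': 455 +/- 104 vs 404 +/- 135"
esv_baseline_response,143,61,18,159,84,15,responders,non-responders,"cohort characteristics table, row 'End-systolic volume (ml)': 143 +/- 61 vs 159 +/- 84"
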