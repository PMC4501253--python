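name,a,b,c,d,row_factor,col_factor,source
t2cl_response,11,1,7,14,T2CL present/absent,responder/non-responder,"cohort characteristics table, row 'Combined type II pattern and concordant CRT lead': 12 (36) overall; 11 (61) responders; 1 (7) non-responders"
type2_response,14,6,4,9,type II/type I pattern,responder/non-responder,"cohort characteristics table, row 'Type II pattern': 20 (61) overall; 14 (78) responders; 6 (40) non-responders"
concordant_response,13,5,5,10,concordant/remote lead,responder/non-responder,"cohort characteristics table, row 'Concordant CRT lead': 18 (55) overall; 13 (72) responders; 5 (28) non-responders"
nicm_response,17,1,9,6,NICM present/absent,responder/non-responder,"cohort characteristics table, row 'NICM': 26 (79) overall; 17 (94) responders; 9 (60) non-responders"
cad_response,2,8,16,7,CAD present/absent,responder/non-responder,"cohort characteristics table, row 'Coronary artery disease': 10 (30) overall; 2 (11) responders; 8 (53) non-responders"
flash_response,17,1,10,5,septal flash present/absent,responder/non-responder,"cohort characteristics table, row 'Septal flash': 27 (82) overall; 17 (94) responders; 10 (67) non-responders"
favorable_ecg_response,9,4,9,11,favorable/non-favorable ECG,responder/non-responder,"cohort characteristics table, row 'Favorable ECG pattern': 13 (39) overall; 9 (50) responders; 4 (27) non-responders"
ecg_pattern,11,9,2,11,type II/type I pattern,favorable/non-favorable ECG,"pattern associations table, rows 'Favorable'/'Non-favorable': 2 (15) type I vs 11 (55) type II"
scar_pattern,2,18,6,7,type II/type I pattern,scar/no scar,"pattern associations table, rows 'Scar'/'No scar': 6 (46) type I vs 2 (10) type II"
flash_pattern,20,0,7,6,type II/type I pattern,flash present/absent,"pattern associations table, rows 'Present'/'Absent': 7 (54) type I vs 20 (100) type II"
nicm_pattern,18,2,8,5,type II/type I pattern,NICM/ICM,"pattern associations table, rows 'NICM'/'ICM': 8 (62) type I vs 18 (90) type II"
concordant_pattern,12,8,6,7,type II/type I pattern,concordant/remote lead,"pattern associations table, rows 'Lead concordant'/'Lead remote': 6 (46) type I vs 12 (60) type II"
nonfavorable_ecg_t2cl_response,6,1,3,10,T2CL present/absent,responder/non-responder,"ECG-pattern results text: within 20 non-favorable-ECG patients, T2CL response 86 % versus 23 %; unique integer solution 6/7 vs 3/13 with 9 responders"
noscar_t2cl_response,11,1,5,8,T2CL present/absent,responder/non-responder,"LGE results text: within 25 no-significant-scar patients, T2CL response 92 % versus 39 %; unique integer solution 11/12 vs 5/13 with 16 responders"
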