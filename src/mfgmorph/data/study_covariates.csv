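sample_id,age_years,infant_sex,breastfeeding_months,birth_status,storage_days,diluted
1,38,Female,3.3,Full-term,28,No
2,35,Female,18.8,Full-term,17.8,Yes
3,35,Female,3.2,Full-term,19.2,Yes
4,41,Male,12.5,Full-term,19.5,Yes
5,34,Male,5.4,Full-term,24.3,Yes
6,37,Female,5.9,Full-term,11,No
7,35,Female,5.9,Full-term,16.5,No
8,34,Female,12.5,Full-term,11.5,No
9,41,Male,1.3,Preterm,7,No
10,37,Male,14.6,Full-term,7,No
11,19,Male,0.3,Preterm,7,No
12,24,Female,1.5,Preterm,7,No
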