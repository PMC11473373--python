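study_id,n,indicator_name,polarity,r_pa_re,r_pa_mh,r_re_mh,population,shares_sample_with
Cocozza 2020,1182,SWB,positive,0.150,0.240,0.46,Adult,
Cui 2022,1048,negative indicator,negative,0.301,-0.357,-0.366,Undergraduate,
Ho 2015,775,positive indicator,positive,0.250,0.660,0.440,Middle school student,
Li 2022,1009,life satisfaction,positive,0.234,0.218,0.618,Elementary school students,
Li 2021,1214,negative indicator,negative,0.470,-0.250,-0.330,Undergraduate,
Liu 2020,1408,negative indicator,negative,0.253,-0.357,-0.355,Undergraduate,
Wu 2023,1248,positive indicator,positive,0.290,0.210,0.590,Adult,
Wu 2022,402,positive indicator,positive,0.386,0.180,0.570,Adult,
Xin 2023,451,anxiety,negative,0.269,-0.301,-0.237,Older adult,
Xu 2018a,2282,life satisfaction,positive,0.297,0.123,0.254,Middle school student,Xu 2018b
Xu 2018b,2282,negative indicator,negative,0.297,-0.137,-0.258,Middle school student,Xu 2018a
Yang 2021,557,SWB,positive,0.36,0.382,0.353,Older people,
Zhang 2023,3143,SWB,positive,0.249,0.247,0.467,Adolescent,
Zhang 2018,485,depression,negative,0.219,-0.315,-0.393,Older adult,
Zhang 2022,1117,negative indicator,negative,0.098,-0.087,-0.304,Undergraduate,
Zhou 2022,722,SWB,positive,0.19,0.187,0.341,Undergraduate,
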