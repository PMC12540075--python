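dimension,factor,predictor,B,se,beta,t,p,tolerance,vif,is_reference
life_assistance,constant,constant,2.789,0.082,,34.126,0.000,,,0
life_assistance,age_band,age_66_70,-0.062,0.092,-0.036,-0.678,0.498,0.746,1.341,0
life_assistance,age_band,age_71_80,0.215,0.087,0.140,2.488,0.013,0.654,1.528,0
life_assistance,age_band,age_ge81,0.287,0.137,0.128,2.098,0.037,0.558,1.792,0
life_assistance,age_band,age_60_65,0,,,,,,,1
life_assistance,education,education_high,0.265,0.081,0.157,3.266,0.001,0.897,1.115,0
life_assistance,education,education_low,0,,,,,,,1
life_assistance,spouse,spouse_none,0.206,0.098,0.128,2.095,0.037,0.553,1.808,0
life_assistance,spouse,spouse_yes,0,,,,,,,1
life_assistance,living_alone,living_alone,0.381,0.115,0.198,3.301,0.001,0.575,1.740,0
life_assistance,living_alone,not_living_alone,0,,,,,,,1
life_assistance,self_care,disabled,0.403,0.111,0.221,3.642,0.000,0.565,1.771,0
life_assistance,self_care,independent,0,,,,,,,1
life_assistance,chronic,chronic,0.170,0.076,0.106,2.240,0.026,0.922,1.084,0
life_assistance,chronic,no_chronic,0,,,,,,,1
medical_care,constant,constant,2.707,0.099,,27.478,0.000,,,0
medical_care,age_band,age_66_70,-0.167,0.101,-0.083,-1.647,0.101,0.736,1.359,0
medical_care,age_band,age_71_80,0.258,0.097,0.145,2.667,0.008,0.633,1.579,0
medical_care,age_band,age_ge81,0.151,0.153,0.058,0.988,0.324,0.541,1.850,0
medical_care,age_band,age_60_65,0,,,,,,,1
medical_care,education,education_high,0.399,0.093,0.205,4.284,0.000,0.820,1.220,0
medical_care,education,education_low,0,,,,,,,1
medical_care,spouse,spouse_none,0.326,0.108,0.176,3.012,0.003,0.553,1.809,0
medical_care,spouse,spouse_yes,0,,,,,,,1
medical_care,living_alone,living_alone,0.294,0.128,0.133,2.296,0.022,0.564,1.772,0
medical_care,living_alone,not_living_alone,0,,,,,,,1
medical_care,self_care,disabled,0.545,0.121,0.259,4.486,0.000,0.565,1.771,0
medical_care,self_care,independent,0,,,,,,,1
medical_care,chronic,chronic,0.253,0.083,0.137,3.036,0.003,0.922,1.084,0
medical_care,chronic,no_chronic,0,,,,,,,1
medical_care,children,children_ge2,-0.207,0.079,-0.124,-2.608,0.010,0.835,1.197,0
medical_care,children,children_le1,0,,,,,,,1
spiritual_cultural,constant,constant,3.202,0.098,,32.808,0.000,,,0
spiritual_cultural,age_band,age_66_70,-0.150,0.125,-0.068,-1.198,0.232,0.736,1.358,0
spiritual_cultural,age_band,age_71_80,0.344,0.119,0.177,2.879,0.004,0.635,1.574,0
spiritual_cultural,age_band,age_ge81,0.045,0.188,0.016,0.241,0.810,0.545,1.836,0
spiritual_cultural,age_band,age_60_65,0,,,,,,,1
spiritual_cultural,education,education_high,0.379,0.114,0.178,3.327,0.001,0.837,1.195,0
spiritual_cultural,education,education_low,0,,,,,,,1
spiritual_cultural,spouse,spouse_none,0.169,0.133,0.083,1.268,0.206,0.558,1.793,0
spiritual_cultural,spouse,spouse_yes,0,,,,,,,1
spiritual_cultural,living_alone,living_alone,0.533,0.158,0.220,3.375,0.001,0.565,1.769,0
spiritual_cultural,living_alone,not_living_alone,0,,,,,,,1
spiritual_cultural,self_care,disabled,0.162,0.147,0.070,1.100,0.272,0.588,1.700,0
spiritual_cultural,self_care,independent,0,,,,,,,1
spiritual_cultural,children,children_ge2,-0.249,0.098,-0.136,-2.538,0.012,0.835,1.197,0
spiritual_cultural,children,children_le1,0,,,,,,,1
rights_protection,constant,constant,2.986,0.122,,24.514,0.000,,,0
rights_protection,age_band,age_66_70,-0.371,0.125,-0.165,-2.954,0.003,0.736,1.359,0
rights_protection,age_band,age_71_80,0.081,0.120,0.041,0.674,0.501,0.633,1.579,0
rights_protection,age_band,age_ge81,-0.465,0.189,-0.161,-2.460,0.014,0.541,1.850,0
rights_protection,age_band,age_60_65,0,,,,,,,1
rights_protection,education,education_high,0.512,0.115,0.236,4.445,0.000,0.820,1.220,0
rights_protection,education,education_low,0,,,,,,,1
rights_protection,spouse,spouse_none,0.105,0.134,0.051,0.784,0.434,0.553,1.809,0
rights_protection,spouse,spouse_yes,0,,,,,,,1
rights_protection,living_alone,living_alone,0.330,0.158,0.133,2.087,0.038,0.564,1.772,0
rights_protection,living_alone,not_living_alone,0,,,,,,,1
rights_protection,self_care,disabled,0.551,0.150,0.234,3.665,0.000,0.565,1.771,0
rights_protection,self_care,independent,0,,,,,,,1
rights_protection,chronic,chronic,0.146,0.103,0.071,1.420,0.156,0.922,1.084,0
rights_protection,chronic,no_chronic,0,,,,,,,1
rights_protection,children,children_ge2,-0.290,0.098,-0.155,-2.949,0.003,0.835,1.197,0
rights_protection,children,children_le1,0,,,,,,,1
age_friendly,constant,constant,3.420,0.216,,15.844,0.000,,,0
age_friendly,age_band,age_66_70,-0.414,0.140,-0.168,-2.952,0.003,0.744,1.344,0
age_friendly,age_band,age_71_80,0.055,0.134,0.025,0.412,0.681,0.641,1.561,0
age_friendly,age_band,age_ge81,-0.321,0.214,-0.101,-1.498,0.135,0.532,1.879,0
age_friendly,age_band,age_60_65,0,,,,,,,1
age_friendly,education,education_high,0.458,0.131,0.192,3.491,0.001,0.799,1.252,0
age_friendly,education,education_low,0,,,,,,,1
age_friendly,spouse,spouse_none,0.324,0.151,0.143,2.148,0.032,0.548,1.825,0
age_friendly,spouse,spouse_yes,0,,,,,,,1
age_friendly,living_alone,living_alone,0.071,0.176,0.026,0.405,0.686,0.574,1.742,0
age_friendly,living_alone,not_living_alone,0,,,,,,,1
age_friendly,self_care,disabled,0.697,0.170,0.270,4.106,0.000,0.558,1.793,0
age_friendly,self_care,independent,0,,,,,,,1
age_friendly,chronic,chronic,0.187,0.117,0.083,1.599,0.111,0.905,1.105,0
age_friendly,chronic,no_chronic,0,,,,,,,1
age_friendly,income_band,income_1501_3000,-0.408,0.195,-0.196,-2.093,0.037,0.275,3.639,0
age_friendly,income_band,income_3001_4999,-0.368,0.199,-0.170,-1.849,0.065,0.286,3.498,0
age_friendly,income_band,income_gt5000,-0.726,0.226,-0.258,-3.214,0.001,0.376,2.662,0
age_friendly,income_band,income_0_1500,0,,,,,,,1
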