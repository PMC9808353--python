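age_group,from_state,HEALTHY,MILD,MODERATE,SEVERE,DEATH
65-69,HEALTHY,0.8982,0.0444,0.0061,0.0052,0.0461
70-74,HEALTHY,0.8283,0.0505,0.0140,0.0117,0.0956
75-79,HEALTHY,0.7425,0.0675,0.0124,0.0195,0.1581
80-84,HEALTHY,0.6395,0.0866,0.0199,0.0301,0.2239
85+,HEALTHY,0.3293,0.1039,0.0341,0.0501,0.4826
65-69,MILD,0.4000,0.5000,0.0000,0.0000,0.1000
70-74,MILD,0.5652,0.1739,0.0435,0.0000,0.2174
75-79,MILD,0.3696,0.1739,0.0652,0.0652,0.3261
80-84,MILD,0.3295,0.1591,0.0227,0.1364,0.3523
85+,MILD,0.0909,0.1114,0.0499,0.0755,0.6723
65-69,MODERATE,0.6000,0.0000,0.0000,0.4000,0.0000
70-74,MODERATE,0.2500,0.1250,0.0000,0.0000,0.6250
75-79,MODERATE,0.0833,0.0833,0.1667,0.2500,0.4167
80-84,MODERATE,0.1111,0.0741,0.0741,0.2963,0.4444
85+,MODERATE,0.0405,0.0358,0.0576,0.1028,0.7632
65-69,SEVERE,0.0000,0.0000,0.0000,0.2500,0.7500
70-74,SEVERE,0.1875,0.0625,0.0625,0.1250,0.5625
75-79,SEVERE,0.0714,0.0000,0.0000,0.2857,0.6429
80-84,SEVERE,0.0313,0.0313,0.0313,0.1875,0.7188
85+,SEVERE,0.0296,0.0178,0.0178,0.0607,0.8743
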