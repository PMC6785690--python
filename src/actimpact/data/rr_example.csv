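outcome,category,rr,ci_low,ci_high,women_only
breast_cancer,<600,1.35,1.18,1.54,True
breast_cancer,600-3999,1.20,1.08,1.33,True
breast_cancer,4000-7999,1.08,0.99,1.18,True
breast_cancer,>=8000,1.0,1.0,1.0,True
colon_cancer,<600,1.45,1.24,1.70,False
colon_cancer,600-3999,1.25,1.10,1.42,False
colon_cancer,4000-7999,1.10,0.99,1.22,False
colon_cancer,>=8000,1.0,1.0,1.0,False
diabetes,<600,1.60,1.38,1.85,False
diabetes,600-3999,1.35,1.19,1.53,False
diabetes,4000-7999,1.12,1.01,1.24,False
diabetes,>=8000,1.0,1.0,1.0,False
ihd,<600,1.42,1.26,1.60,False
ihd,600-3999,1.24,1.12,1.37,False
ihd,4000-7999,1.10,1.00,1.21,False
ihd,>=8000,1.0,1.0,1.0,False
stroke,<600,1.48,1.28,1.71,False
stroke,600-3999,1.28,1.13,1.45,False
stroke,4000-7999,1.11,1.00,1.23,False
stroke,>=8000,1.0,1.0,1.0,False
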